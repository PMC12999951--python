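"""Sequence and annotation I/O plus per-position labelling.

Reads replicons (FASTA / GenBank) and CDS annotations (GFF3 / GenBank),
normalizes everything to 0-based half-open coordinates, and builds the
per-position label map (codon position, strand coverage) that all skew
computations consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


class Topology(str, Enum):
    circular = "circular"
    linear = "linear"


class Completeness(str, Enum):
    complete = "complete"
    draft = "draft"
    unknown = "unknown"


class Strand(str, Enum):
    plus = "+"
    minus = "-"


@dataclass(frozen=True)
class Replicon:
    """A single DNA sequence with identifier, length and topology.

    The sequence is stored upper-case over the alphabet {A, C, G, T, N}.
    """

    id: str
    sequence: str
    topology: Topology = Topology.circular
    completeness: Completeness = Completeness.unknown

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"replicon {self.id!r}: empty sequence")
        seq = self.sequence.upper()
        bad = set(seq) - VALID_BASES
        if bad:
            pos = next(i for i, b in enumerate(seq) if b in bad)
            raise ValueError(
                f"replicon {self.id!r}: invalid character {seq[pos]!r} "
                f"at position {pos + 1} (1-based)"
            )
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "Replicon":
        rc = self.sequence.encode()[::-1].translate(_COMPLEMENT).decode()
        return Replicon(self.id, rc, self.topology, self.completeness)


@dataclass(frozen=True)
class CdsFeature:
    """A CDS interval in 0-based half-open coordinates.

    ``frame_offset`` is the number of bases to skip (at the 5' end of the
    coding strand) before the first complete codon, i.e. the GFF3 phase.
    """

    replicon_id: str
    start: int
    end: int
    strand: Strand
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"feature on {self.replicon_id!r}: invalid interval "
                f"[{self.start}, {self.end})"
            )
        if self.frame_offset not in (0, 1, 2):
            raise ValueError(f"frame_offset must be 0, 1 or 2, got {self.frame_offset}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def labels_codons(self) -> bool:
        """Whether this feature is long enough to contribute codon labels."""
        return (self.end - self.start - self.frame_offset) >= 3


@dataclass
class FeatureTable:
    """An ordered collection of CdsFeature records for one replicon."""

    features: list[CdsFeature] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def __getitem__(self, i):
        return self.features[i]

    def for_replicon(self, replicon_id: str) -> "FeatureTable":
        return FeatureTable([f for f in self.features if f.replicon_id == replicon_id])


@dataclass
class PositionLabelMap:
    """Per-position codon-position labels and strand coverage.

    ``codon_label[p]`` is 0 for non-coding positions and 1/2/3 for the codon
    position of the highest-priority CDS labelling p.  ``strand_cover[p]`` is
    +1 when p is covered only by plus-strand features, -1 only by minus-strand
    features, and 0 otherwise.  ``label_strand[p]`` records the strand
    (+1/-1/0) of the feature that supplied the codon label, used by the
    gene-oriented counting mode.
    """

    replicon_id: str
    codon_label: np.ndarray
    strand_cover: np.ndarray
    label_strand: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.codon_label)
        if len(self.strand_cover) != n or len(self.label_strand) != n:
            raise ValueError("label arrays must have equal length")


# ---------------------------------------------------------------------------
# readers


def _completeness_from_annotations(record) -> Completeness:
    text = " ".join(
        str(v)
        for k, v in record.annotations.items()
        if k in ("comment", "data_file_division", "keywords")
    ).lower()
    desc = (record.description or "").lower()
    if "complete" in text or "complete" in desc:
        return Completeness.complete
    return Completeness.unknown


def read_replicons(
    path: str | Path,
    format: str = "fasta",
    default_topology: Topology = Topology.circular,
) -> list[Replicon]:
    """Read one Replicon per record from a FASTA or GenBank file.

    Lower-case bases are folded to upper case.  Topology and completeness are
    taken from GenBank annotations when present, otherwise the configured
    default topology is used.
    """
    path = Path(path)
    if format not in ("fasta", "genbank"):
        raise ValueError(f"unsupported sequence format {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    replicons: list[Replicon] = []
    for record in SeqIO.parse(str(path), format):
        seq = str(record.seq)
        if not seq:
            raise ValueError(f"record {record.id!r} in {path} is empty")
        topology = default_topology
        completeness = Completeness.unknown
        if format == "genbank":
            topo = record.annotations.get("topology", "")
            if topo in ("circular", "linear"):
                topology = Topology(topo)
            completeness = _completeness_from_annotations(record)
        replicons.append(
            Replicon(record.id, seq, topology=topology, completeness=completeness)
        )
    if not replicons:
        raise ValueError(f"no sequence records found in {path}")
    return replicons


def _parse_gff3(
    path: Path,
    feature_type: str,
    replicon_lengths: dict[str, int] | None,
    strict: bool,
) -> list[CdsFeature]:
    features: list[CdsFeature] = []
    n_dropped_strand = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            seqid, _, ftype, start_s, end_s, _, strand_s, phase_s, _ = cols
            if ftype != feature_type:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if strand_s not in ("+", "-"):
                n_dropped_strand += 1
                continue
            phase = int(phase_s) if phase_s in ("0", "1", "2") else 0
            start, end = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
            if replicon_lengths is not None:
                length = replicon_lengths.get(seqid)
                if length is not None and end > length:
                    msg = f"{path}:{lineno}: feature end {end} beyond replicon length {length}"
                    if strict:
                        raise ValueError(msg)
                    logger.warning("%s; feature dropped", msg)
                    continue
            features.append(
                CdsFeature(seqid, start, end, Strand(strand_s), frame_offset=phase)
            )
    if n_dropped_strand:
        logger.info("dropped %d features on unknown strand", n_dropped_strand)
    return features


def _genbank_cds_parts(record, feature_type: str) -> Iterable[CdsFeature]:
    for feat in record.features:
        if feat.type != feature_type:
            continue
        if feat.location is None or feat.location.strand not in (1, -1):
            continue
        strand = Strand.plus if feat.location.strand == 1 else Strand.minus
        parts = sorted(feat.location.parts, key=lambda p: int(p.start))
        # frame applies at the 5' end of the coding strand; carry it across
        # join() parts in coding order.
        coding_order = parts if strand is Strand.plus else parts[::-1]
        consumed = 0
        out = []
        for part in coding_order:
            plen = int(part.end) - int(part.start)
            offset = (3 - consumed % 3) % 3 if consumed % 3 else 0
            out.append(
                CdsFeature(record.id, int(part.start), int(part.end), strand, offset)
            )
            consumed += plen
        yield from (out if strand is Strand.plus else out[::-1])


def read_features(
    path: str | Path,
    format: str = "gff3",
    feature_type: str = "CDS",
    replicon_lengths: dict[str, int] | None = None,
    strict: bool = False,
) -> FeatureTable:
    """Read CDS features from GFF3 or GenBank into 0-based half-open records.

    GFF3 phase is mapped to ``frame_offset``.  Features on an unknown strand
    are dropped (with a logged count).  Features whose end exceeds the
    replicon length are dropped with a warning, or raise in strict mode.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "gff3":
        return FeatureTable(_parse_gff3(path, feature_type, replicon_lengths, strict))
    if format == "genbank":
        features: list[CdsFeature] = []
        for record in SeqIO.parse(str(path), "genbank"):
            features.extend(_genbank_cds_parts(record, feature_type))
        return FeatureTable(features)
    raise ValueError(f"unsupported annotation format {format!r}")


def write_features_gff3(
    features: FeatureTable, path: str | Path, feature_type: str = "CDS"
) -> None:
    """Write a FeatureTable as GFF3 (coordinates converted back to 1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                "\t".join(
                    [
                        f.replicon_id,
                        "repliskew",
                        feature_type,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand.value,
                        str(f.frame_offset),
                        ".",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# position labelling


def _priority_order(features: Sequence[CdsFeature]) -> list[CdsFeature]:
    # Lowest priority first so the highest-priority feature writes last.
    # Priority: longer feature wins; ties broken by smaller start.
    return sorted(features, key=lambda f: (len(f), -f.start))


def build_position_labels(replicon: Replicon, features: FeatureTable) -> PositionLabelMap:
    """Build codon-position labels and strand coverage for one replicon.

    A plus-strand feature labels position p in [start+frame, end) with
    ``1 + ((p - start - frame) % 3)``; a minus-strand feature labels it with
    ``1 + ((end - 1 - frame - p) % 3)`` (codons read 5'->3' on the minus
    strand).  Overlapping labels are resolved in favour of the longer
    feature (ties: smaller start).  ``strand_cover`` is +1/-1 only for
    positions covered exclusively by one strand.
    """
    n = replicon.length
    codon_label = np.zeros(n, dtype=np.int8)
    label_strand = np.zeros(n, dtype=np.int8)
    plus_cover = np.zeros(n, dtype=bool)
    minus_cover = np.zeros(n, dtype=bool)

    feats = [f for f in features if f.replicon_id == replicon.id]
    if len(feats) != len(features.features):
        extra = {f.replicon_id for f in features} - {replicon.id}
        if extra:
            raise ValueError(
                f"features for unknown replicon(s) {sorted(extra)} "
                f"passed with replicon {replicon.id!r}"
            )

    for f in feats:
        if f.end > n:
            raise ValueError(
                f"feature [{f.start}, {f.end}) out of bounds for "
                f"replicon {replicon.id!r} of length {n}"
            )
        if f.strand is Strand.plus:
            plus_cover[f.start : f.end] = True
        else:
            minus_cover[f.start : f.end] = True

    for f in _priority_order(feats):
        if not f.labels_codons:
            continue
        if f.strand is Strand.plus:
            lo = f.start + f.frame_offset
            pos = np.arange(lo, f.end)
            labels = 1 + (pos - lo) % 3
        else:
            hi = f.end - f.frame_offset
            pos = np.arange(f.start, hi)
            labels = 1 + (hi - 1 - pos) % 3
        codon_label[pos] = labels
        label_strand[pos] = 1 if f.strand is Strand.plus else -1

    strand_cover = np.where(
        plus_cover & ~minus_cover, 1, np.where(minus_cover & ~plus_cover, -1, 0)
    ).astype(np.int8)
    return PositionLabelMap(replicon.id, codon_label, strand_cover, label_strand)
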