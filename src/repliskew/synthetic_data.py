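"""Synthetic circular replicons with known replication and gene-strand structure.

The generator writes composition directly at its expected equilibrium rather
than forward-simulating mutation: it partitions the circle into two
replichores around a chosen origin, places non-overlapping genes with a
tunable bias toward co-orientation with the local leading strand, samples
coding positions from codon-position-specific nucleotide weights (on the
coding strand), fills intergenic sequence from a background GC content, and
finally applies a strand-specific C->G enrichment of the leading strand
(attenuated at codon positions 1-2 to mimic selective constraint).

Everything is deterministic given the seed, and the emitted FASTA/GFF3 pair
is consumed unchanged by :mod:`repliskew.genome_io`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .genome_io import (
    CdsFeature,
    FeatureTable,
    Replicon,
    Strand,
    Topology,
    Completeness,
    write_features_gff3,
)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP_IDX = np.array([3, 2, 1, 0])  # A<->T, C<->G in ACGT index space


def default_codon_weights() -> np.ndarray:
    """Per-codon-position nucleotide probabilities (rows: pos 1-3; cols ACGT).

    Position 1 is G-enriched, position 2 favours T and A (with C above G),
    position 3 is uniform.  Values are illustrative defaults chosen to
    reproduce the qualitative sign structure of coding-position skews, not
    estimates from any genome.
    """
    w = np.array(
        [
            [0.20, 0.20, 0.40, 0.20],  # pos 1: G preferred
            [0.30, 0.20, 0.10, 0.40],  # pos 2: T/A preferred, C > G
            [0.25, 0.25, 0.25, 0.25],  # pos 3: neutral
        ]
    )
    return w / w.sum(axis=1, keepdims=True)


@dataclass
class SyntheticConfig:
    length: int = 1_048_576
    ori_position: int = 0
    leading_fraction: float = 0.5
    beta: float = 0.05
    p_lead: float = 0.75
    gene_density: float = 0.85
    mean_gene_length: int = 300  # codons
    codon_weights: np.ndarray = field(default_factory=default_codon_weights)
    intergenic_gc: float = 0.5
    coding_attenuation: float = 0.25  # beta multiplier at codon positions 1-2
    seed: int = 0

    def validate(self) -> None:
        if self.length < 8 * 4096:
            raise ValueError("length must be at least 8 windows of 4096 bases")
        if not 0 <= self.ori_position < self.length:
            raise ValueError("ori_position must lie within the replicon")
        if not 0 < self.leading_fraction < 1:
            raise ValueError("leading_fraction must be in (0, 1)")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not 0 <= self.p_lead <= 1:
            raise ValueError("p_lead must be in [0, 1]")
        if not 0 < self.gene_density < 1:
            raise ValueError("gene_density must be in (0, 1)")
        if self.mean_gene_length < 1:
            raise ValueError("mean_gene_length must be >= 1 codon")
        w = np.asarray(self.codon_weights, dtype=float)
        if w.shape != (3, 4) or not np.allclose(w.sum(axis=1), 1.0):
            raise ValueError("codon_weights must be three probability 4-vectors")
        if not 0 < self.intergenic_gc < 1:
            raise ValueError("intergenic_gc must be in (0, 1)")

    def to_json(self) -> str:
        d = asdict(self)
        d["codon_weights"] = np.asarray(self.codon_weights).tolist()
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticConfig":
        d = json.loads(text)
        if "codon_weights" in d:
            d["codon_weights"] = np.asarray(d["codon_weights"], dtype=float)
        return cls(**d)


@dataclass
class GroundTruth:
    true_div: float
    ori_bp: int
    ter_bp: int
    beta: float
    p_lead: float
    genes: list[dict]  # start, end, strand, replichore, co_oriented

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


def _place_genes(cfg: SyntheticConfig, rng: np.random.Generator):
    """Non-overlapping genes around the circle, leaving the origin point clear."""
    mean_gene_bp = 3 * cfg.mean_gene_length
    mean_gap = max(1.0, mean_gene_bp * (1 - cfg.gene_density) / cfg.gene_density)
    if mean_gene_bp + mean_gap > cfg.length / 2:
        raise ValueError("infeasible gene density / length combination")
    genes = []
    pos = int(rng.integers(0, int(2 * mean_gap) + 1))
    while True:
        n_codons = 1 + rng.geometric(1.0 / cfg.mean_gene_length)
        glen = 3 * n_codons
        if pos + glen > cfg.length:
            break  # no wrap-around genes
        genes.append((pos, pos + glen))
        pos += glen + 1 + int(rng.geometric(1.0 / mean_gap))
    return genes


def simulate_replicon(
    cfg: SyntheticConfig, replicon_id: str = "synthetic"
) -> tuple[Replicon, FeatureTable, GroundTruth]:
    """Generate one annotated circular replicon plus its ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.length
    ori = cfg.ori_position
    ter = (ori + int(round(cfg.leading_fraction * n))) % n

    # replichore 1 = arc ori->ter (plus strand leading), replichore 2 = rest
    pos_idx = np.arange(n)
    on_arc1 = ((pos_idx - ori) % n) < ((ter - ori) % n)
    # reference-strand leading flag: +1 where plus strand is leading
    plus_is_leading = on_arc1

    gene_bounds = _place_genes(cfg, rng)
    strands = []
    gene_truth = []
    for start, end in gene_bounds:
        mid = (start + end) // 2
        leading_strand = Strand.plus if plus_is_leading[mid] else Strand.minus
        co = rng.random() < cfg.p_lead
        strand = leading_strand if co else (
            Strand.minus if leading_strand is Strand.plus else Strand.plus
        )
        strands.append(strand)
        gene_truth.append(
            {
                "start": int(start),
                "end": int(end),
                "strand": strand.value,
                "replichore": 1 if plus_is_leading[mid] else 2,
                "co_oriented": bool(co),
            }
        )

    # sequence as ACGT indices
    seq_idx = np.empty(n, dtype=np.int8)
    gc = cfg.intergenic_gc
    bg = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq_idx[:] = rng.choice(4, size=n, p=bg)

    w = np.asarray(cfg.codon_weights, dtype=float)
    codon_pos = np.zeros(n, dtype=np.int8)  # 0 = intergenic, 1..3 codon position
    # sample every codon of every gene in three vectorized draws
    codons_per_gene = [(end - start) // 3 for start, end in gene_bounds]
    k_total = sum(codons_per_gene)
    pools = [rng.choice(4, size=k_total, p=w[p]) for p in range(3)]
    offset = 0
    for (start, end), strand, k in zip(gene_bounds, strands, codons_per_gene):
        coding = np.stack([pool[offset : offset + k] for pool in pools], axis=1).ravel()
        offset += k
        labels = np.tile([1, 2, 3], k)
        if strand is Strand.plus:
            seq_idx[start:end] = coding
            codon_pos[start:end] = labels
        else:
            seq_idx[start:end] = _COMP_IDX[coding[::-1]]
            codon_pos[start:end] = labels[::-1]

    # strand-specific mutational bias: net G enrichment of the leading strand
    if cfg.beta > 0:
        p_flip = np.where(
            (codon_pos == 1) | (codon_pos == 2),
            cfg.beta * cfg.coding_attenuation,
            cfg.beta,
        )
        hit = rng.random(n) < p_flip
        # plus strand leading: reference C -> G; minus strand leading: the
        # leading-strand C is a reference G, so reference G -> C.
        c_on_lead = np.where(plus_is_leading, seq_idx == 1, seq_idx == 2)
        flip = hit & c_on_lead
        seq_idx[flip & plus_is_leading] = 2
        seq_idx[flip & ~plus_is_leading] = 1

    sequence = BASES[seq_idx].tobytes().decode()
    replicon = Replicon(
        replicon_id, sequence, topology=Topology.circular, completeness=Completeness.complete
    )
    features = FeatureTable(
        [
            CdsFeature(replicon_id, start, end, strand, frame_offset=0)
            for (start, end), strand in zip(gene_bounds, strands)
        ]
    )
    truth = GroundTruth(
        true_div=cfg.leading_fraction,
        ori_bp=ori + 1,
        ter_bp=ter + 1,
        beta=cfg.beta,
        p_lead=cfg.p_lead,
        genes=gene_truth,
    )
    return replicon, features, truth


def write_synthetic(
    cfg: SyntheticConfig, out_dir: str | Path, replicon_id: str = "synthetic"
) -> tuple[Path, Path, Path]:
    """Emit FASTA + GFF3 + ground-truth JSON; returns the three paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    replicon, features, truth = simulate_replicon(cfg, replicon_id)
    fasta = out_dir / f"{replicon_id}.fasta"
    with open(fasta, "w") as fh:
        fh.write(f">{replicon.id} synthetic circular replicon\n")
        for i in range(0, replicon.length, 80):
            fh.write(replicon.sequence[i : i + 80] + "\n")
    gff = out_dir / f"{replicon_id}.gff3"
    write_features_gff3(features, gff)
    truth_path = out_dir / f"{replicon_id}.truth.json"
    truth_path.write_text(truth.to_json())
    return fasta, gff, truth_path
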