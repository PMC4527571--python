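"""Synthetic two-library small-RNA experiment with full ground truth.

The generator emulates the design the pipeline is built for: two pooled
small-RNA libraries from the same organism under two conditions (named
CA and NA by default), a genome carrying planted miRNA precursors that
fold into stem-loops, a miRBase-style mature reference for the known
subset, structural-RNA references whose fragments contaminate the
libraries, and a transcript set with complementary target sites whose
differential expression is inversely or positively coupled to the
targeting miRNA.

Every quantity the pipeline later estimates — per-miRNA abundance,
log2 fold change, DE direction, precursor locus, target relation — is
recorded in a truth table, so parameter recovery is testable end to end.
All randomness flows from one integer seed through a single
``numpy.random.Generator``; a fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from mirmodule._seq import revcomp, write_collapsed_fasta, write_fasta

_BASES = np.array(list("ACGT"))

#: Read-length mixture of the background small-RNA population.  The two
#: modes mirror a typical plant library: a dominant 21 nt class (canonical
#: miRNA/siRNA length) and a secondary 24 nt class (heterochromatic
#: siRNAs).
DEFAULT_LENGTH_MIXTURE = {
    18: 0.02, 19: 0.03, 20: 0.06, 21: 0.49, 22: 0.08, 23: 0.07, 24: 0.17,
    25: 0.03, 26: 0.02, 27: 0.01, 28: 0.01, 29: 0.005, 30: 0.005,
}

#: Fractions of total reads drawn from each structural-RNA reference;
#: the remainder of the non-miRNA mass is unannotated background.
DEFAULT_STRUCTURAL_FRACTIONS = {"rRNA": 0.35, "tRNA": 0.03, "snRNA": 0.002, "snoRNA": 0.001}


@dataclass
class FoldChangeDistribution:
    """Two-condition effect-size model for miRNA abundances."""

    fraction_up: float = 0.45
    fraction_down: float = 0.30
    magnitude_min: float = 1.5
    magnitude_max: float = 4.0


@dataclass
class SimulationConfig:
    """All knobs of the synthetic experiment.

    Defaults are desk-scale study conditions: two libraries of 10^5
    reads, 60 known and 20 novel miRNAs carrying ~4% of the reads, and
    negative-binomial count noise with mild overdispersion (pooled
    biological material is overdispersed relative to Poisson even
    without replicates).
    """

    seed: int = 0
    n_known: int = 60
    n_novel: int = 20
    genome_length: int = 120_000
    depth_A: int = 100_000
    depth_B: int = 100_000
    fc_distribution: FoldChangeDistribution = field(default_factory=FoldChangeDistribution)
    noise_model: str = "negative_binomial"  # or "poisson"
    dispersion: float = 0.05
    length_mixture: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_MIXTURE)
    )
    mirna_fraction: float = 0.04
    structural_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STRUCTURAL_FRACTIONS)
    )
    library_A: str = "CA"
    library_B: str = "NA"
    mature_length: int = 21
    loop_range: tuple[int, int] = (8, 15)
    star_mutations_max: int = 2
    targets_per_mirna_max: int = 2
    hub_inverse_targets: int = 0  # give the strongest up-miRNA this many inverse targets
    n_background_genes: int = 40
    transcript_length: int = 400
    epsilon: float = 0.01  # floor used for truth-table log2 fold changes
    n_decoy_refs: int = 10  # unexpressed extra family members in the mature reference

    def validate(self) -> None:
        fc = self.fc_distribution
        if not (0 <= fc.fraction_up <= 1 and 0 <= fc.fraction_down <= 1):
            raise ValueError("fold-change fractions must lie in [0, 1]")
        if fc.fraction_up + fc.fraction_down > 1:
            raise ValueError("fold-change fractions must sum to at most 1")
        if self.depth_A <= 0 or self.depth_B <= 0:
            raise ValueError("library depths must be positive")
        if self.genome_length < 50 * (self.n_known + self.n_novel):
            raise ValueError(
                "genome too small: need at least 50 nt per planted precursor"
            )
        weights = np.array(list(self.length_mixture.values()))
        if weights.min() < 0 or not np.isclose(weights.sum(), 1.0):
            raise ValueError("length mixture weights must be non-negative and sum to 1")
        if self.noise_model not in ("negative_binomial", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


@dataclass
class MirnaTruth:
    """Ground truth for one simulated miRNA."""

    mirna_id: str
    mirna_class: str  # "known" or "novel"
    chrom: str
    precursor_start: int
    precursor_end: int
    strand: str
    mature_seq: str
    true_abundance_A: float
    true_abundance_B: float
    true_log2fc: float
    target_gene_ids: list[str] = field(default_factory=list)
    target_relation: str = "none"  # inverse, positive or none

    @property
    def direction(self) -> str:
        if self.true_log2fc > 1:
            return "up"
        if self.true_log2fc < -1:
            return "down"
        return "unDE"


@dataclass
class SyntheticDataset:
    """Everything one simulation run produces."""

    config: SimulationConfig
    genome: dict[str, str]
    truth: list[MirnaTruth]
    mature_reference: dict[str, str]  # miRBase-style known mature FASTA records
    structural_references: dict[str, dict[str, str]]  # category -> id -> seq
    libraries: dict[str, Counter] = field(default_factory=dict)  # lib -> seq -> count
    transcripts: dict[str, str] = field(default_factory=dict)
    gene_de: pd.DataFrame | None = None

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for t in self.truth:
            rows.append(
                {
                    "mirna_id": t.mirna_id,
                    "class": t.mirna_class,
                    "chrom": t.chrom,
                    "precursor_start": t.precursor_start,
                    "precursor_end": t.precursor_end,
                    "strand": t.strand,
                    "mature_seq": t.mature_seq,
                    "true_abundance_A": t.true_abundance_A,
                    "true_abundance_B": t.true_abundance_B,
                    "true_log2fc": t.true_log2fc,
                    "direction": t.direction,
                    "target_gene_ids": ",".join(t.target_gene_ids),
                    "target_relation": t.target_relation,
                }
            )
        return pd.DataFrame(rows)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _mutate(rng: np.random.Generator, seq: str, n_mut: int) -> str:
    s = list(seq)
    for pos in rng.choice(len(s), size=n_mut, replace=False):
        current = s[pos]
        s[pos] = str(rng.choice([b for b in "ACGT" if b != current]))
    return "".join(s)


def _build_precursor(rng: np.random.Generator, cfg: SimulationConfig) -> tuple[str, str, int]:
    """Mature + loop + mutated reverse complement; returns (precursor, mature, offset)."""
    mature = _random_seq(rng, cfg.mature_length)
    star = _mutate(rng, revcomp(mature), int(rng.integers(0, cfg.star_mutations_max + 1)))
    loop = _random_seq(rng, int(rng.integers(cfg.loop_range[0], cfg.loop_range[1] + 1)))
    return mature + loop + star, mature, 0


def _draw_log2fc(rng: np.random.Generator, fc: FoldChangeDistribution) -> float:
    u = rng.random()
    mag = rng.uniform(fc.magnitude_min, fc.magnitude_max)
    if u < fc.fraction_up:
        return mag
    if u < fc.fraction_up + fc.fraction_down:
        return -mag
    return 0.0


def simulate_genome(config: SimulationConfig) -> tuple[dict[str, str], list[MirnaTruth]]:
    """Build the genome with planted precursors and the truth table.

    Known and novel precursors are placed at non-overlapping positions on
    a uniform random background, on either strand; every mature sequence
    is an exact substring of its precursor on its strand.  Abundances are
    log-normal around an equal share of the miRNA read mass, and fold
    changes follow the configured up/down/null mixture.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chrom = "chr1"
    n_total = config.n_known + config.n_novel

    genome = list(_random_seq(rng, config.genome_length))
    truth: list[MirnaTruth] = []

    # evenly spaced slots with jitter keep precursors non-overlapping
    slot = config.genome_length // max(n_total, 1) if n_total else config.genome_length
    # log-normal abundance weights, normalised so the reference-condition
    # miRNA mass matches the configured fraction of the library
    weights = rng.lognormal(mean=0.0, sigma=1.0, size=n_total) if n_total else np.array([])
    if n_total:
        weights = weights / weights.sum() * config.mirna_fraction * config.depth_A
    seen_matures: set[str] = set()
    for i in range(n_total):
        known = i < config.n_known
        while True:
            precursor, mature, _ = _build_precursor(rng, config)
            if mature not in seen_matures:
                seen_matures.add(mature)
                break
        start = i * slot + int(rng.integers(0, max(1, slot - len(precursor) - 1)))
        end = start + len(precursor)
        strand = "+" if rng.random() < 0.5 else "-"
        planted = precursor if strand == "+" else revcomp(precursor)
        genome[start:end] = list(planted)

        abundance_a = float(weights[i])
        log2fc = _draw_log2fc(rng, config.fc_distribution)
        abundance_b = abundance_a * 2.0**log2fc
        eps = config.epsilon
        truth.append(
            MirnaTruth(
                mirna_id=(f"tch-miR{1000 + i}" if known else f"novel_candidate_{i - config.n_known + 1}"),
                mirna_class="known" if known else "novel",
                chrom=chrom,
                precursor_start=start,
                precursor_end=end,
                strand=strand,
                mature_seq=mature,
                true_abundance_A=abundance_a,
                true_abundance_B=abundance_b,
                true_log2fc=float(np.log2((abundance_b + eps) / (abundance_a + eps))),
            )
        )

    if config.hub_inverse_targets > 0:
        _designate_hub(truth, config)
    _assign_targets(rng, truth, config)
    return {chrom: "".join(genome)}, truth


def _designate_hub(truth: list[MirnaTruth], config: SimulationConfig) -> None:
    """Force one known miRNA up with high abundance; it will get the hub targets."""
    known = [t for t in truth if t.mirna_class == "known"]
    hub = max(known, key=lambda t: t.true_abundance_A)
    hub.true_log2fc = 3.0
    hub.true_abundance_A = max(hub.true_abundance_A, 200.0)
    hub.true_abundance_B = hub.true_abundance_A * 8.0
    eps = config.epsilon
    hub.true_log2fc = float(
        np.log2((hub.true_abundance_B + eps) / (hub.true_abundance_A + eps))
    )


def _assign_targets(
    rng: np.random.Generator, truth: list[MirnaTruth], config: SimulationConfig
) -> None:
    gene_counter = 0

    def next_gene() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"gene{gene_counter:04d}"

    hub_idx: int | None = None
    if config.hub_inverse_targets > 0:
        known = [i for i, t in enumerate(truth) if t.mirna_class == "known"]
        hub_idx = max(known, key=lambda i: truth[i].true_abundance_A)

    for i, t in enumerate(truth):
        if i == hub_idx:
            t.target_relation = "inverse"
            t.target_gene_ids = [next_gene() for _ in range(config.hub_inverse_targets)]
            continue
        n_targets = int(rng.integers(0, config.targets_per_mirna_max + 1))
        if n_targets == 0:
            continue
        t.target_gene_ids = [next_gene() for _ in range(n_targets)]
        if t.direction == "unDE":
            t.target_relation = "none"
        else:
            u = rng.random()
            t.target_relation = "inverse" if u < 0.5 else ("positive" if u < 0.75 else "none")


def simulate_references(config: SimulationConfig, truth: list[MirnaTruth]) -> tuple[
    dict[str, str], dict[str, dict[str, str]]
]:
    """Mature-miRNA and structural-RNA reference sets.

    The mature reference holds every known mature sequence under its
    miRBase-style id plus a few unexpressed same-family decoys (variant
    letter b) so family-representative selection is exercised.
    Structural references are random molecules of realistic lengths.
    """
    rng = np.random.default_rng(config.seed + 1)
    mature: dict[str, str] = {}
    known = [t for t in truth if t.mirna_class == "known"]
    for t in known:
        mature[f"{t.mirna_id}a"] = t.mature_seq
    for t in known[: config.n_decoy_refs]:
        mature[f"{t.mirna_id}b"] = _mutate(rng, t.mature_seq, 2)
    structural = {
        "rRNA": {f"rRNA_{i+1}": _random_seq(rng, 1500) for i in range(2)},
        "tRNA": {f"tRNA_{i+1}": _random_seq(rng, 75) for i in range(5)},
        "snRNA": {f"snRNA_{i+1}": _random_seq(rng, 150) for i in range(3)},
        "snoRNA": {f"snoRNA_{i+1}": _random_seq(rng, 100) for i in range(3)},
    }
    return mature, structural


def _draw_count(rng: np.random.Generator, mu: float, config: SimulationConfig) -> int:
    if mu <= 0:
        return 0
    if config.noise_model == "poisson" or config.dispersion <= 0:
        return int(rng.poisson(mu))
    n = 1.0 / config.dispersion
    p = n / (n + mu)
    return int(rng.negative_binomial(n, p))


def _background_pool(
    rng: np.random.Generator,
    config: SimulationConfig,
    forbidden: set[str],
    pool_size: int,
) -> tuple[list[str], np.ndarray]:
    """Unique background tags with log-normal sampling weights.

    Tags colliding with planted mature sequences are re-sampled so truth
    assignment stays unambiguous.
    """
    lengths = np.array(list(config.length_mixture.keys()))
    weights = np.array(list(config.length_mixture.values()))
    pool: list[str] = []
    seen = set(forbidden)
    while len(pool) < pool_size:
        length = int(rng.choice(lengths, p=weights))
        seq = _random_seq(rng, length)
        if seq in seen:
            continue
        seen.add(seq)
        pool.append(seq)
    return pool, rng.lognormal(mean=0.0, sigma=1.5, size=pool_size)


def _structural_pool(
    rng: np.random.Generator,
    config: SimulationConfig,
    references: Mapping[str, Mapping[str, str]],
    forbidden: set[str],
) -> dict[str, tuple[list[str], np.ndarray]]:
    pools: dict[str, tuple[list[str], np.ndarray]] = {}
    lengths = np.array(list(config.length_mixture.keys()))
    weights = np.array(list(config.length_mixture.values()))
    for category in sorted(references):
        records = references[category]
        seqs: list[str] = []
        n_frags = 60
        ids = sorted(records)
        attempts = 0
        while len(seqs) < n_frags and attempts < 50 * n_frags:
            attempts += 1
            src = records[ids[int(rng.integers(0, len(ids)))]]
            length = int(rng.choice(lengths, p=weights))
            if length >= len(src):
                continue
            start = int(rng.integers(0, len(src) - length + 1))
            frag = src[start : start + length]
            if frag in forbidden:
                continue
            seqs.append(frag)
        pools[category] = (seqs, rng.lognormal(mean=0.0, sigma=1.0, size=len(seqs)))
    return pools


def simulate_libraries(
    truth: list[MirnaTruth],
    config: SimulationConfig,
    references: Mapping[str, Mapping[str, str]] | None = None,
) -> dict[str, Counter]:
    """Draw the two read multisets.

    Per-miRNA counts come from the configured noise model around the
    true abundances; structural fragments and unannotated background
    tags fill the remaining depth from shared pools, so both libraries
    see the same background tag universe with independent counts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2)
    matures = {t.mature_seq for t in truth}
    if references is None:
        references = {}

    depths = {config.library_A: config.depth_A, config.library_B: config.depth_B}
    bg_pool, bg_weights = _background_pool(
        rng, config, matures, pool_size=max(2000, config.depth_A // 20)
    )
    structural_pools = _structural_pool(rng, config, references, matures)

    libraries: dict[str, Counter] = {}
    for lib in sorted(depths):
        depth = depths[lib]
        counts: Counter = Counter()
        mirna_total = 0
        for t in truth:
            mu = t.true_abundance_A if lib == config.library_A else t.true_abundance_B
            c = _draw_count(rng, mu, config)
            if c:
                counts[t.mature_seq] += c
                mirna_total += c
        remaining = max(0, depth - mirna_total)
        for category in sorted(structural_pools):
            frac = config.structural_fractions.get(category, 0.0)
            n_cat = int(round(frac * depth))
            seqs, w = structural_pools[category]
            if not seqs or n_cat == 0:
                continue
            n_cat = min(n_cat, remaining)
            draw = rng.multinomial(n_cat, w / w.sum())
            for seq, c in zip(seqs, draw):
                if c:
                    counts[seq] += int(c)
            remaining -= n_cat
        if remaining > 0:
            draw = rng.multinomial(remaining, bg_weights / bg_weights.sum())
            nz = np.nonzero(draw)[0]
            for idx in nz:
                counts[bg_pool[idx]] += int(draw[idx])
        libraries[lib] = counts
    return libraries


def simulate_transcripts(truth: list[MirnaTruth], config: SimulationConfig) -> dict[str, str]:
    """Transcripts for target scanning: one per target gene plus background.

    Each target transcript carries the exact reverse complement of its
    miRNA at a random interior position; background genes carry no
    planted site.
    """
    rng = np.random.default_rng(config.seed + 3)
    transcripts: dict[str, str] = {}
    for t in truth:
        for gene in t.target_gene_ids:
            body = _random_seq(rng, config.transcript_length)
            site = revcomp(t.mature_seq)
            pos = int(rng.integers(50, config.transcript_length - len(site) - 50))
            transcripts[gene] = body[:pos] + site + body[pos + len(site):]
    for i in range(config.n_background_genes):
        transcripts[f"bg_gene{i + 1:04d}"] = _random_seq(rng, config.transcript_length)
    return transcripts


def simulate_mrna_de(truth: list[MirnaTruth], config: SimulationConfig) -> pd.DataFrame:
    """Gene-level DE table coupled to the miRNA truth.

    Genes in inverse modules move opposite to their miRNA, positive
    modules move with it, and uncoupled genes (relation none, or
    background) are unDE.  Duplicate gene assignments are rejected.
    """
    rng = np.random.default_rng(config.seed + 4)
    rows = []
    seen: set[str] = set()
    for t in truth:
        if not t.target_gene_ids:
            continue
        for gene in t.target_gene_ids:
            if gene in seen:
                raise ValueError(f"duplicate gene id {gene}")
            seen.add(gene)
            if t.target_relation == "inverse" and t.direction in ("up", "down"):
                status = "down" if t.direction == "up" else "up"
            elif t.target_relation == "positive" and t.direction in ("up", "down"):
                status = t.direction
            else:
                status = "unDE"
            if status == "unDE":
                log2fc = float(rng.normal(0.0, 0.3))
                p = float(rng.uniform(0.2, 1.0))
            else:
                mag = float(rng.uniform(1.5, 4.0))
                log2fc = mag if status == "up" else -mag
                p = float(rng.uniform(1e-8, 1e-3))
            rows.append({"gene_id": gene, "log2fc": log2fc, "p": p, "fdr": min(1.0, p * 2), "status": status})
    for i in range(config.n_background_genes):
        rows.append(
            {
                "gene_id": f"bg_gene{i + 1:04d}",
                "log2fc": float(rng.normal(0.0, 0.3)),
                "p": float(rng.uniform(0.2, 1.0)),
                "fdr": 1.0,
                "status": "unDE",
            }
        )
    return pd.DataFrame(rows)


def simulate_all(config: SimulationConfig) -> SyntheticDataset:
    """Run the full generator and return every artefact."""
    genome, truth = simulate_genome(config)
    mature_ref, structural = simulate_references(config, truth)
    libraries = simulate_libraries(truth, config, references=structural)
    transcripts = simulate_transcripts(truth, config)
    gene_de = simulate_mrna_de(truth, config)
    return SyntheticDataset(
        config=config,
        genome=genome,
        truth=truth,
        mature_reference=mature_ref,
        structural_references=structural,
        libraries=libraries,
        transcripts=transcripts,
        gene_de=gene_de,
    )


# ---------------------------------------------------------------------------
# writers


def write_dataset(dataset: SyntheticDataset, outdir: str | Path, fastq: bool = False) -> dict[str, Path]:
    """Write every artefact of a simulation to *outdir*; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genome"] = outdir / "genome.fa"
    write_fasta(sorted(dataset.genome.items()), paths["genome"])

    paths["mature_reference"] = outdir / "mature_reference.fa"
    write_fasta(sorted(dataset.mature_reference.items()), paths["mature_reference"])

    for category, records in sorted(dataset.structural_references.items()):
        key = f"ref_{category}"
        paths[key] = outdir / f"{category}.fa"
        write_fasta(sorted(records.items()), paths[key])

    for lib, counts in sorted(dataset.libraries.items()):
        key = f"reads_{lib}"
        items = sorted(counts.items(), key=lambda x: (-x[1], x[0]))
        if fastq:
            paths[key] = outdir / f"{lib}.fq"
            with open(paths[key], "w") as out:
                read_no = 0
                for seq, count in items:
                    for _ in range(count):
                        read_no += 1
                        out.write(f"@{lib}_read{read_no}\n{seq}\n+\n{'I' * len(seq)}\n")
        else:
            paths[key] = outdir / f"{lib}.fa"
            write_collapsed_fasta(items, paths[key])

    paths["truth"] = outdir / "truth.tsv"
    dataset.truth_table().to_csv(paths["truth"], sep="\t", index=False)

    if dataset.transcripts:
        paths["transcripts"] = outdir / "transcripts.fa"
        write_fasta(sorted(dataset.transcripts.items()), paths["transcripts"])
    if dataset.gene_de is not None:
        paths["gene_de"] = outdir / "gene_de.tsv"
        dataset.gene_de.to_csv(paths["gene_de"], sep="\t", index=False)
    return paths
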