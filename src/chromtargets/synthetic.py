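"""Synthetic multi-factor ChIP/RNA study with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so that every recovered quantity can be checked against a known
truth:

* genes carry latent occupancy by three complexes — TRHT/TRHD (the
  TRB-containing complexes, treated as one co-occupying unit), PEAT
  (active chromatin) and PRC2 (Polycomb). PEAT occupancy is positively
  coupled to TRHT/TRHD occupancy; PRC2 occupancy is drawn preferentially
  on genes NOT occupied by PEAT (weighted sampling), so the two mark
  largely disjoint chromatin states;
* each factor of an occupied complex emits a TSS-proximal peak with a
  configurable detection probability, and gene-level binding counts are
  negative-binomial around a per-gene per-complex strength shared by the
  complex's factors (which is what makes within-complex signals correlate);
* wild-type H3K4me3 baselines are ordered PEAT-shared > specific >
  PRC2-shared by default; per mutant genotype a configurable fraction of
  each target subclass receives a planted fold-change increase of the
  mark, optionally coupled to a planted expression increase;
* two DNA motifs are written into peak sequences from a joint presence
  distribution with a configurable co-occurrence excess over independence.

A single master seed feeds named substreams per stage, so any stage can be
regenerated independently and identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import CountMatrix, GeneModel, Peak
from .motifs import PWM, revcomp

TRHT_TRHD_FACTORS = ("TRB1", "ICU11", "HTH1", "ZDP2")
PEAT_FACTORS = ("EPCR2", "UBP5", "PWWP1")
PRC2_FACTORS = ("LHP1",)

COMPLEX_FACTORS: dict[str, tuple[str, ...]] = {
    "TRHT_TRHD": TRHT_TRHD_FACTORS,
    "PEAT": PEAT_FACTORS,
    "PRC2": PRC2_FACTORS,
}

_STAGE_IDS = {"genome": 1, "binding": 2, "marks": 3, "expression": 4, "motifs": 5}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _STAGE_IDS[stage]]))


@dataclass(frozen=True)
class SimConfig:
    """Study-level simulation parameters.

    Occupancy probabilities default to genome fractions of roughly a
    quarter for TRHT/TRHD and PEAT and a sixth for PRC2, mirroring the
    relative scale of the three regulons in Arabidopsis. H3K4me3 baselines
    (wild-type RPKM) are ordered PEAT-shared > non-target > specific >
    PRC2-shared, reflecting the intermediate chromatin state of
    complex-specific targets.
    """

    n_genes: int = 6000
    n_chromosomes: int = 2
    gene_length_range: tuple[int, int] = (1000, 3000)
    intergenic_gap_range: tuple[int, int] = (1500, 3000)
    chromosome_cap: int | None = None
    complex_occupancy_probs: Mapping[str, float] = field(
        default_factory=lambda: {"TRHT_TRHD": 0.245, "PEAT": 0.249, "PRC2": 0.162}
    )
    peat_given_trht_boost: float = 1.8
    prc2_peat_weight: float = 0.2
    factor_detection_prob: float = 0.9
    mark_baseline: Mapping[str, float] = field(
        default_factory=lambda: {
            "peat_shared": 30.0, "specific": 10.0, "prc2_shared": 3.0, "nontarget": 12.0,
        }
    )
    expression_baseline: Mapping[str, float] = field(
        default_factory=lambda: {
            "peat_shared": 25.0, "specific": 8.0, "prc2_shared": 2.0, "nontarget": 12.0,
        }
    )
    mark_effect_fc: float = 3.0
    expression_effect_fc: float = 3.0
    planted_fraction_per_subclass: Mapping[str, float] = field(
        default_factory=lambda: {
            "peat_shared": 0.05, "specific": 0.17, "prc2_shared": 0.29,
        }
    )
    expression_coupling: float = 0.6
    background_expression_change_prob: float = 0.01
    genotypes: tuple[str, ...] = ("jmj14",)
    nb_dispersion: float = 0.1
    n_replicates: int = 2
    library_size: int = 2_000_000
    motif_marginals: tuple[float, float] = (0.4, 0.3)
    motif_cooccurrence_excess: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [
            *self.complex_occupancy_probs.values(),
            self.factor_detection_prob,
            *self.planted_fraction_per_subclass.values(),
            self.expression_coupling,
            self.background_expression_change_prob,
            *self.motif_marginals,
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.mark_effect_fc <= 0 or self.expression_effect_fc <= 0:
            raise ValueError("fold changes must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if set(self.complex_occupancy_probs) != set(COMPLEX_FACTORS):
            raise ValueError(
                f"complex_occupancy_probs must name exactly {sorted(COMPLEX_FACTORS)}"
            )


@dataclass
class SyntheticTruth:
    """Planted parameters the pipeline is later asked to recover."""

    occupancy: pd.DataFrame  # gene x {TRHT_TRHD, PEAT, PRC2} booleans + subclass
    planted_marks: pd.DataFrame | None = None  # gene x genotype booleans (mark up)
    planted_expression: pd.DataFrame | None = None  # gene x genotype in {-1, 0, +1}
    motif_classes: dict[str, str] | None = None  # peak_id -> planted class
    motif_placements: pd.DataFrame | None = None  # peak_id, motif_id, offset, strand

    def subclass_members(self, name: str) -> set[str]:
        occ = self.occupancy
        return set(occ.index[occ["subclass"] == name])

    def target_genes(self) -> set[str]:
        return set(self.occupancy.index[self.occupancy["TRHT_TRHD"]])


# ---------------------------------------------------------------------------
# genome

def simulate_genome(cfg: SimConfig) -> tuple[list[GeneModel], dict[str, str]]:
    """Lay out non-overlapping genes and draw uniform background sequence.

    Genes alternate strand at random and are separated by uniform gaps;
    every chromosome keeps >= 2 kb clear flank at both ends.
    """
    rng = _rng(cfg.seed, "genome")
    lo_len, hi_len = cfg.gene_length_range
    lo_gap, hi_gap = cfg.intergenic_gap_range
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_genes // cfg.n_chromosomes)
    per_chrom[: cfg.n_genes % cfg.n_chromosomes] += 1

    genes: list[GeneModel] = []
    seqs: dict[str, str] = {}
    gi = 0
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        pos = 2000
        for _ in range(int(per_chrom[ci])):
            length = int(rng.integers(lo_len, hi_len + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"g{gi:05d}", chrom, pos, pos + length, strand))
            gi += 1
            pos += length + int(rng.integers(lo_gap, hi_gap + 1))
        chrom_len = pos + 2000
        if cfg.chromosome_cap is not None and chrom_len > cfg.chromosome_cap:
            raise ValueError(
                f"{chrom}: required length {chrom_len} bp exceeds the "
                f"chromosome cap {cfg.chromosome_cap} bp"
            )
        bases = rng.integers(0, 4, size=chrom_len)
        seqs[chrom] = (
            np.frombuffer(b"ACGT", dtype=np.uint8)[bases].tobytes().decode()
        )
    return genes, seqs


# ---------------------------------------------------------------------------
# binding

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with Var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    r = 1.0 / dispersion
    p = r / (r + np.maximum(mean, 1e-12))
    out = rng.negative_binomial(r, p)
    return np.where(mean <= 0, 0, out)


def _subclass_labels(occ: pd.DataFrame) -> pd.Series:
    """One label per gene for baseline assignment.

    Subclasses downstream are non-exclusive, but baselines need a single
    value; dual-shared genes take the PRC2-shared (repressed) baseline
    because Polycomb dominates the chromatin state.
    """
    lab = pd.Series("nontarget", index=occ.index)
    t = occ["TRHT_TRHD"]
    lab[t] = "specific"
    lab[t & occ["PEAT"]] = "peat_shared"
    lab[t & occ["PRC2"]] = "prc2_shared"
    return lab


def simulate_binding(
    cfg: SimConfig, genes: Sequence[GeneModel]
) -> tuple[dict[str, list[Peak]], CountMatrix, SyntheticTruth]:
    """Draw latent occupancy, per-factor peaks and gene-level binding counts."""
    rng = _rng(cfg.seed, "binding")
    n = len(genes)
    gene_ids = [g.gene_id for g in genes]
    p_trht = cfg.complex_occupancy_probs["TRHT_TRHD"]
    p_peat = cfg.complex_occupancy_probs["PEAT"]
    p_prc2 = cfg.complex_occupancy_probs["PRC2"]

    trht = rng.random(n) < p_trht
    # PEAT enriched on TRHT/TRHD genes, marginal preserved
    p_given = min(1.0, p_peat * cfg.peat_given_trht_boost)
    p_not = (p_peat - p_trht * p_given) / (1 - p_trht) if p_trht < 1 else 0.0
    if p_not < 0:
        raise ValueError("peat_given_trht_boost incompatible with the marginals")
    peat = rng.random(n) < np.where(trht, p_given, p_not)
    # PRC2 avoids PEAT genes: weighted sampling without replacement of a
    # binomial number of genes (rejection-style negative coupling)
    n_prc2 = rng.binomial(n, p_prc2)
    weights = np.where(peat, cfg.prc2_peat_weight, 1.0)
    prc2 = np.zeros(n, dtype=bool)
    if n_prc2 > 0:
        chosen = rng.choice(n, size=n_prc2, replace=False, p=weights / weights.sum())
        prc2[chosen] = True

    occ = pd.DataFrame(
        {"TRHT_TRHD": trht, "PEAT": peat, "PRC2": prc2}, index=pd.Index(gene_ids)
    )
    occ["subclass"] = _subclass_labels(occ)
    truth = SyntheticTruth(occupancy=occ)

    # shared per-gene per-complex strength drives within-complex correlation
    strength = {c: np.exp(rng.normal(0.0, 0.5, n)) for c in COMPLEX_FACTORS}
    occupied = {"TRHT_TRHD": trht, "PEAT": peat, "PRC2": prc2}
    len_kb = np.array([g.length / 1e3 for g in genes])
    scale = len_kb * cfg.library_size / 1e6

    peaks: dict[str, list[Peak]] = {}
    counts: dict[str, np.ndarray] = {}
    for cname, factors in COMPLEX_FACTORS.items():
        signal = np.where(occupied[cname], 20.0 * strength[cname], 0.5)
        for f in factors:
            counts[f] = _nb_draw(rng, signal * scale, cfg.nb_dispersion)
            plist: list[Peak] = []
            detected = occupied[cname] & (rng.random(n) < cfg.factor_detection_prob)
            ups = rng.integers(100, 251, size=n)
            downs = rng.integers(150, 351, size=n)
            for i in np.flatnonzero(detected):
                g = genes[i]
                tss = g.tss
                if g.strand == "+":
                    start, end = tss - int(ups[i]), tss + int(downs[i])
                else:
                    start, end = tss - int(downs[i]) + 1, tss + int(ups[i]) + 1
                plist.append(
                    Peak(f"{f}_{g.gene_id}", g.chrom, max(0, start), end,
                         round(float(signal[i]), 3))
                )
            peaks[f] = plist

    all_factors = [f for fs in COMPLEX_FACTORS.values() for f in fs]
    cm = CountMatrix(
        pd.DataFrame({f: counts[f] for f in all_factors}, index=pd.Index(gene_ids)),
        pd.Series(cfg.library_size, index=all_factors),
    )
    return peaks, cm, truth


# ---------------------------------------------------------------------------
# marks and expression

def simulate_marks_and_expression(
    cfg: SimConfig,
    genes: Sequence[GeneModel],
    truth: SyntheticTruth,
) -> tuple[dict[str, CountMatrix], dict[str, CountMatrix], SyntheticTruth]:
    """H3K4me3 and RNA count matrices for WT and each mutant genotype.

    Returns (mark_counts, rna_counts), each keyed by 'WT' and the genotype
    names, with ``cfg.n_replicates`` columns per matrix, plus the truth
    updated with the planted mark/expression changes.
    """
    if cfg.n_replicates < 2:
        raise ValueError("differential calling requires n_replicates >= 2")
    rng = _rng(cfg.seed, "marks")
    gene_ids = [g.gene_id for g in genes]
    n = len(genes)
    sub = truth.occupancy["subclass"].to_numpy()
    len_kb = np.array([g.length / 1e3 for g in genes])
    scale = len_kb * cfg.library_size / 1e6

    mark_mu_wt = np.array([cfg.mark_baseline[s] for s in sub]) * np.exp(
        rng.normal(0.0, 0.25, n)
    )
    expr_mu_wt = np.array([cfg.expression_baseline[s] for s in sub]) * np.exp(
        rng.normal(0.0, 0.4, n)
    )

    planted_marks = pd.DataFrame(False, index=pd.Index(gene_ids), columns=list(cfg.genotypes))
    planted_expr = pd.DataFrame(0, index=pd.Index(gene_ids), columns=list(cfg.genotypes))
    plant_p = np.array(
        [cfg.planted_fraction_per_subclass.get(s, 0.0) for s in sub]
    )
    for gt in cfg.genotypes:
        mark_up = rng.random(n) < plant_p
        planted_marks[gt] = mark_up
        expr_dir = np.zeros(n, dtype=int)
        expr_dir[mark_up & (rng.random(n) < cfg.expression_coupling)] = 1
        bg = rng.random(n) < cfg.background_expression_change_prob
        bg &= expr_dir == 0
        expr_dir[bg] = np.where(rng.random(bg.sum()) < 0.5, 1, -1)
        planted_expr[gt] = expr_dir

    def draw(mu: np.ndarray) -> CountMatrix:
        cols = {}
        for r in range(cfg.n_replicates):
            cols[f"rep{r + 1}"] = _nb_draw(rng, mu * scale, cfg.nb_dispersion)
        df = pd.DataFrame(cols, index=pd.Index(gene_ids))
        return CountMatrix(df, pd.Series(cfg.library_size, index=df.columns))

    mark_counts = {"WT": draw(mark_mu_wt)}
    rna_counts = {"WT": draw(expr_mu_wt)}
    for gt in cfg.genotypes:
        mu_m = mark_mu_wt * np.where(planted_marks[gt].to_numpy(), cfg.mark_effect_fc, 1.0)
        dirs = planted_expr[gt].to_numpy()
        mu_e = expr_mu_wt * np.where(
            dirs > 0, cfg.expression_effect_fc,
            np.where(dirs < 0, 1.0 / cfg.expression_effect_fc, 1.0),
        )
        mark_counts[gt] = draw(mu_m)
        rna_counts[gt] = draw(mu_e)

    truth = replace(truth, planted_marks=planted_marks, planted_expression=planted_expr)
    return mark_counts, rna_counts, truth


# ---------------------------------------------------------------------------
# motifs

def default_pwms() -> tuple[PWM, PWM]:
    """Two illustrative near-consensus PWMs.

    A telobox-like motif (AAACCCTA, the telomere-repeat-like sequence bound
    by TRB Myb domains) and a NAC-binding-like motif (TTGCGTGT). These are
    stand-ins with 0.91 consensus-base probability per column, not matrices
    fitted to any ChIP data.
    """

    def near_consensus(motif_id: str, consensus: str) -> PWM:
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        m = np.full((4, len(consensus)), 0.03)
        for j, b in enumerate(consensus):
            m[idx[b], j] = 0.91
        return PWM(motif_id, m)

    return near_consensus("telobox", "AAACCCTA"), near_consensus("nac", "TTGCGTGT")


def joint_presence_probs(
    marginal_a: float, marginal_b: float, excess: float
) -> tuple[float, float, float, float]:
    """(both, a_only, b_only, neither) probabilities for peak motif status."""
    p_both = excess * marginal_a * marginal_b
    if p_both > min(marginal_a, marginal_b) + 1e-12:
        raise ValueError(
            "requested marginals and co-occurrence excess are infeasible: "
            "P(both) exceeds a marginal"
        )
    p_neither = 1.0 - marginal_a - marginal_b + p_both
    if p_neither < -1e-12:
        raise ValueError("marginals and excess leave negative P(neither)")
    return (p_both, marginal_a - p_both, marginal_b - p_both, max(0.0, p_neither))


def plant_motifs(
    cfg: SimConfig,
    peaks: Sequence[Peak],
    sequences: Mapping[str, str],
    pwm_a: PWM,
    pwm_b: PWM,
) -> tuple[dict[str, str], SyntheticTruth]:
    """Write motif consensi into peak sequences from a joint distribution.

    Presence of each motif per peak follows the configured marginals and
    co-occurrence excess; planted instances are the PWM consensus at a
    uniform offset and strand inside the peak (two motifs in one peak never
    overlap). Returns the edited sequences and a truth record of the
    planted classes and placements.
    """
    pa, pb = cfg.motif_marginals
    probs = joint_presence_probs(pa, pb, cfg.motif_cooccurrence_excess)
    min_width = min(p.end - p.start for p in peaks) if peaks else 0
    if peaks and max(pwm_a.length, pwm_b.length) >= min_width:
        raise ValueError("PWM consensus must be shorter than the narrowest peak")
    rng = _rng(cfg.seed, "motifs")
    edited = {c: bytearray(s.encode()) for c, s in sequences.items()}
    classes: dict[str, str] = {}
    placements: list[dict] = []
    labels = ("both", "a_only", "b_only", "neither")

    def place(peak: Peak, pwm: PWM, forbidden: tuple[int, int] | None) -> tuple[int, str]:
        width = peak.end - peak.start
        for _ in range(100):
            off = int(rng.integers(0, width - pwm.length + 1))
            if forbidden and off < forbidden[1] and forbidden[0] < off + pwm.length:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            word = pwm.consensus if strand == "+" else revcomp(pwm.consensus)
            edited[peak.chrom][peak.start + off: peak.start + off + pwm.length] = word.encode()
            return off, strand
        raise RuntimeError(f"could not place motif without overlap in {peak.peak_id}")

    for peak in peaks:
        cls = labels[rng.choice(4, p=probs)]
        classes[peak.peak_id] = cls
        occupied: tuple[int, int] | None = None
        if cls in ("both", "a_only"):
            off, strand = place(peak, pwm_a, None)
            occupied = (off, off + pwm_a.length)
            placements.append({"peak_id": peak.peak_id, "motif_id": pwm_a.motif_id,
                               "offset": off, "strand": strand})
        if cls in ("both", "b_only"):
            off, strand = place(peak, pwm_b, occupied)
            placements.append({"peak_id": peak.peak_id, "motif_id": pwm_b.motif_id,
                               "offset": off, "strand": strand})

    truth = SyntheticTruth(
        occupancy=pd.DataFrame(index=pd.Index([], dtype=object)),
        motif_classes=classes,
        motif_placements=pd.DataFrame(
            placements, columns=["peak_id", "motif_id", "offset", "strand"]
        ),
    )
    return {c: b.decode() for c, b in edited.items()}, truth


# ---------------------------------------------------------------------------
# one-call study

@dataclass
class SimulatedStudy:
    config: SimConfig
    genes: list[GeneModel]
    sequences: dict[str, str]
    peaks: dict[str, list[Peak]]
    binding_counts: CountMatrix
    mark_counts: dict[str, CountMatrix]
    rna_counts: dict[str, CountMatrix]
    pwm_a: PWM
    pwm_b: PWM
    truth: SyntheticTruth


def simulate_study(cfg: SimConfig, with_motifs: bool = True) -> SimulatedStudy:
    """Run every stage and merge the per-stage truths."""
    genes, seqs = simulate_genome(cfg)
    peaks, binding, truth = simulate_binding(cfg, genes)
    mark_counts, rna_counts, truth = simulate_marks_and_expression(cfg, genes, truth)
    pwm_a, pwm_b = default_pwms()
    if with_motifs:
        trb1_peaks = peaks["TRB1"]
        seqs, mtruth = plant_motifs(cfg, trb1_peaks, seqs, pwm_a, pwm_b)
        truth = replace(
            truth,
            motif_classes=mtruth.motif_classes,
            motif_placements=mtruth.motif_placements,
        )
    return SimulatedStudy(
        config=cfg, genes=genes, sequences=seqs, peaks=peaks,
        binding_counts=binding, mark_counts=mark_counts, rna_counts=rna_counts,
        pwm_a=pwm_a, pwm_b=pwm_b, truth=truth,
    )
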