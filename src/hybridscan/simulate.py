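"""Synthetic admixed-cohort generator with ground truth.

Emulates the statistical structure the downstream scans assume: a hybrid
zone cohort of admixed individuals in three cross-sectional age classes
(HY/SY/ASY), ancestry informative markers carrying block-wise ancestry
linkage from Markov tracts along each chromosome, age-structured viability
selection acting on locus heterozygosity and pairwise ancestry mismatch, an
optional planted inversion-like region (recombination suppressed in
heterokaryotypes), plus two-valued recombination maps and toy Hi-C contact
matrices with a one-sided long-range interaction.

Each individual carries two haplotypes.  Parental and F1 classes have fixed
haplotype ancestries; backcross and later-generation classes carry
recombinant haplotypes simulated as two-state Markov chains whose switch
probability per inter-locus gap is ``tract_switch_rate * gap_Mb`` scaled to
preserve each haplotype's ancestry proportion.  The later-generation
ancestry proportion is solved from the configured target mean ancestry
(default 0.77 inland, the hybrid-zone average) given the class mixture.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from hybridscan.aim import AimMatrix, SampleMeta

AGE_NAMES = ("HY", "SY", "ASY")

DEFAULT_CHROMOSOMES = (
    ("chr1", 120_000_000, 500, False),
    ("chr2", 80_000_000, 300, False),
    ("chr3", 60_000_000, 250, False),
    ("chr5", 60_000_000, 350, False),
    ("chr12", 20_000_000, 150, False),
    ("chrZ", 70_000_000, 450, True),
)

DEFAULT_ANCESTRY_MIX = {
    "coastal": 0.02,
    "inland": 0.10,
    "f1": 0.03,
    "bc_coastal": 0.03,
    "bc_inland": 0.12,
    "later": 0.70,
}

# mean ancestry contributed by each fixed-structure class
_CLASS_MEAN_Q = {
    "coastal": 0.0,
    "inland": 1.0,
    "f1": 0.5,
    "bc_coastal": 0.25,
    "bc_inland": 0.75,
}


@dataclass
class SelectionTarget:
    """Viability selection on heterozygosity at one locus.

    ``beta_het`` is the additive logit-scale survival effect of being
    heterozygous at the locus; ``beta_int`` multiplies heterozygosity by
    genome-wide ancestry q, making selection strength ancestry-dependent.
    """

    locus: int
    beta_het: float
    beta_int: float = 0.0


@dataclass
class MismatchTarget:
    """Viability selection on ancestry mismatch at a locus pair.

    ``beta_pair`` acts on the pair's mismatch distance d; ``beta_pair_q``
    on d * q, so the cost of mismatch can depend on genome-wide ancestry.
    """

    locus_i: int
    locus_j: int
    beta_pair: float
    beta_pair_q: float = 0.0


@dataclass
class SimConfig:
    """Configuration of the synthetic hybrid-zone cohort.

    Defaults describe the emulated study population: ~900 birds in three
    age classes, ~2,000 AIMs over five autosomes and the Z, mean inland
    ancestry 0.77, and no selection (add targets to plant effects).
    """

    n_individuals: int = 900
    chromosomes: tuple = DEFAULT_CHROMOSOMES
    ancestry_mix: dict = field(default_factory=lambda: dict(DEFAULT_ANCESTRY_MIX))
    target_mean_ancestry: float = 0.77
    tract_switch_rate: float = 0.5  # ancestry switches per Mb per haplotype
    later_concentration: float = 10.0  # Beta concentration of later-gen ancestry
    selection_targets: list[SelectionTarget] = field(default_factory=list)
    mismatch_targets: list[MismatchTarget] = field(default_factory=list)
    survival_base: tuple[float, float] = (0.4, 0.0)  # logit HY->SY, SY->ASY
    age_class_probs: tuple[float, float, float] = (0.5, 0.3, 0.2)
    inversion: tuple[str, int, int] | None = None  # (chrom, start_bp, end_bp)
    inversion_flux: float = 0.08  # per-locus ancestry flip rate in homokaryotypes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")
        if abs(sum(self.ancestry_mix.values()) - 1.0) > 1e-8:
            raise ValueError("ancestry_mix proportions must sum to 1")
        unknown = set(self.ancestry_mix) - set(_CLASS_MEAN_Q) - {"later"}
        if unknown:
            raise ValueError(f"unknown ancestry classes: {sorted(unknown)}")
        if self.tract_switch_rate < 0:
            raise ValueError("tract_switch_rate must be >= 0")
        if not 0 <= self.target_mean_ancestry <= 1:
            raise ValueError("target_mean_ancestry must lie in [0, 1]")
        if abs(sum(self.age_class_probs) - 1.0) > 1e-8:
            raise ValueError("age_class_probs must sum to 1")
        if self.inversion is not None:
            chrom, start, end = self.inversion
            by_label = {c[0]: c for c in self.chromosomes}
            if chrom not in by_label:
                raise ValueError(f"inversion chromosome {chrom!r} not simulated")
            if not (1 <= start < end <= by_label[chrom][1]):
                raise ValueError("inversion interval must lie within its chromosome")

    def later_mean_q(self) -> float:
        """Later-generation ancestry proportion implied by the target mean."""
        f_later = self.ancestry_mix.get("later", 0.0)
        fixed = sum(
            self.ancestry_mix.get(k, 0.0) * v for k, v in _CLASS_MEAN_Q.items()
        )
        if f_later == 0:
            return 0.5  # unused
        p = (self.target_mean_ancestry - fixed) / f_later
        if not 0 < p < 1:
            raise ValueError(
                "target mean ancestry unreachable with the given class mixture"
            )
        return p

    def sorted_chromosomes(self) -> list:
        """Chromosomes in lexicographic label order (the matrix locus order).

        Locus indices in selection and mismatch targets refer to this
        order, which matches :class:`~hybridscan.aim.AimMatrix` sorting.
        """
        return sorted(self.chromosomes, key=lambda c: str(c[0]))

    def locus_table(self) -> pd.DataFrame:
        """Evenly spaced 1-based locus positions per chromosome, sorted."""
        rows = []
        for label, length, n_loci, is_z in self.sorted_chromosomes():
            pos = np.round((np.arange(n_loci) + 0.5) / n_loci * length).astype(np.int64)
            pos = np.maximum(pos, 1)
            for p in pos:
                rows.append({"chrom": label, "pos": int(p), "is_z": bool(is_z)})
        return pd.DataFrame(rows)


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated cohort."""

    selection_targets: list[SelectionTarget]
    mismatch_targets: list[MismatchTarget]
    inversion: tuple[str, int, int] | None
    inversion_genotypes: np.ndarray | None  # karyotype 0/1/2 per individual
    ancestry_class: list[str]
    survived_first: np.ndarray
    survived_second: np.ndarray

    def to_json(self, path) -> None:
        payload = {
            "selection_targets": [asdict(t) for t in self.selection_targets],
            "mismatch_targets": [asdict(t) for t in self.mismatch_targets],
            "inversion": list(self.inversion) if self.inversion else None,
            "inversion_genotypes": (
                self.inversion_genotypes.tolist()
                if self.inversion_genotypes is not None
                else None
            ),
            "ancestry_class": self.ancestry_class,
            "survived_first": self.survived_first.astype(int).tolist(),
            "survived_second": self.survived_second.astype(int).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _simulate_haplotypes(
    rng: np.random.Generator,
    p: np.ndarray,
    fixed: np.ndarray,
    gaps_mb: np.ndarray,
    rate: float,
) -> np.ndarray:
    """Two-state Markov ancestry tracts for a batch of haplotypes.

    ``p`` is each haplotype's inland proportion, ``fixed`` is -1 for
    recombinant haplotypes or 0/1 for fixed parental haplotypes.  The
    transition probabilities per gap preserve the stationary proportion:
    P(0->1) = r*gap*p, P(1->0) = r*gap*(1-p), capped at 1.
    """
    n_hap = p.size
    n_loci = gaps_mb.size + 1
    out = np.empty((n_hap, n_loci), dtype=np.int8)
    state = rng.random(n_hap) < p
    out[:, 0] = state
    for k, gap in enumerate(gaps_mb):
        # capping the rate factor at 1 preserves the stationary proportion p:
        # at r*gap >= 1 the next state is a fresh Bernoulli(p) draw
        r = min(rate * gap, 1.0)
        p01 = r * p
        p10 = r * (1.0 - p)
        u = rng.random(n_hap)
        switch = np.where(state, u < p10, u < p01)
        state = state ^ switch
        out[:, k + 1] = state
    is_fixed = fixed >= 0
    if is_fixed.any():
        out[is_fixed] = fixed[is_fixed, None]
    return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def _candidate_batch(
    rng: np.random.Generator, config: SimConfig, batch: int, loci: pd.DataFrame
):
    """Simulate a batch of candidate individuals with survival draws."""
    classes = list(config.ancestry_mix)
    probs = np.array([config.ancestry_mix[c] for c in classes])
    cls_idx = rng.choice(len(classes), size=batch, p=probs)
    cls = np.array(classes, dtype=object)[cls_idx]

    later_p = config.later_mean_q() if "later" in classes else 0.5
    conc = config.later_concentration
    # per-haplotype inland proportion and fixed-ancestry flag
    p_h = np.full((batch, 2), 0.5)
    fixed = np.full((batch, 2), -1, dtype=np.int8)
    for i, c in enumerate(cls):
        if c == "coastal":
            fixed[i] = (0, 0)
        elif c == "inland":
            fixed[i] = (1, 1)
        elif c == "f1":
            fixed[i] = (0, 1)
        elif c == "bc_coastal":
            fixed[i, 0] = 0
        elif c == "bc_inland":
            fixed[i, 0] = 1
        else:  # later-generation admixed: individual-specific proportion
            q_i = rng.beta(later_p * conc, (1.0 - later_p) * conc)
            p_h[i] = q_i
    p_flat = p_h.reshape(-1)
    fixed_flat = fixed.reshape(-1)

    n_loci_total = len(loci)
    haps = np.empty((batch * 2, n_loci_total), dtype=np.int8)
    col = 0
    inv = config.inversion
    karyotype = None
    for label, length, n_loci, _ in config.sorted_chromosomes():
        sel = slice(col, col + n_loci)
        pos = loci["pos"].to_numpy()[sel]
        gaps_mb = np.diff(pos) / 1e6
        haps[:, sel] = _simulate_haplotypes(
            rng, p_flat, fixed_flat, gaps_mb, config.tract_switch_rate
        )
        if inv is not None and inv[0] == label:
            in_inv = (pos >= inv[1]) & (pos <= inv[2])
            if in_inv.any():
                # haplotype inversion orientation: tied to ancestry proportion
                orient = np.where(
                    fixed_flat >= 0, fixed_flat, (rng.random(batch * 2) < p_flat)
                ).astype(np.int8)
                o = orient.reshape(batch, 2)
                karyotype = o.sum(axis=1)
                hap_block = np.repeat(orient[:, None], int(in_inv.sum()), axis=1)
                # homokaryotypes exchange freely within the region: rare
                # per-locus ancestry flux on recombinant haplotypes only
                hom = (o[:, 0] == o[:, 1]).repeat(2)
                fluxable = hom & (fixed_flat < 0)
                if fluxable.any() and config.inversion_flux > 0:
                    flips = rng.random(hap_block.shape) < config.inversion_flux
                    flips[~fluxable] = False
                    hap_block = hap_block ^ flips
                block = np.zeros((batch * 2, n_loci), dtype=np.int8)
                block[:, in_inv] = hap_block
                haps[:, sel] = np.where(in_inv[None, :], block, haps[:, sel])
        col += n_loci

    states = (haps[0::2] + haps[1::2]).astype(float)
    q = states.mean(axis=1) / 2.0

    logit1 = np.full(batch, config.survival_base[0])
    logit2 = np.full(batch, config.survival_base[1])
    for t in config.selection_targets:
        het = (states[:, t.locus] == 1).astype(float)
        eff = t.beta_het * het + t.beta_int * het * q
        logit1 += eff
        logit2 += eff
    for t in config.mismatch_targets:
        d = np.abs(states[:, t.locus_i] - states[:, t.locus_j]) / np.sqrt(2.0)
        eff = t.beta_pair * d + t.beta_pair_q * d * q
        logit1 += eff
        logit2 += eff
    s1 = rng.random(batch) < _sigmoid(logit1)
    s2 = rng.random(batch) < _sigmoid(logit2)
    return states, cls, karyotype, s1, s2


def simulate_cohort(
    config: SimConfig,
) -> tuple[AimMatrix, SampleMeta, SimTruth]:
    """Simulate a cross-sectional hybrid-zone cohort with viability selection.

    Age-class quotas are drawn from ``age_class_probs``; candidates are
    generated, assigned a prospective age class at random, and accepted
    only if their simulated survival reaches it (SY requires surviving the
    first transition, ASY both).  The accepted cohort therefore has the
    genotype-frequency shifts across age classes that the scans look for.

    Returns ``(matrix, meta, truth)``, reproducible bit-for-bit under
    ``config.seed``.
    """
    root = np.random.SeedSequence(config.seed)
    rng_geno, rng_assign = (np.random.default_rng(s) for s in root.spawn(2))
    loci = config.locus_table()
    n = config.n_individuals
    quotas = rng_assign.multinomial(n, config.age_class_probs)

    kept_states: list[np.ndarray] = []
    kept_age: list[int] = []
    kept_class: list[str] = []
    kept_karyo: list[int] = []
    kept_s1: list[bool] = []
    kept_s2: list[bool] = []
    remaining = quotas.astype(int).copy()
    max_candidates = 400 * n
    n_candidates = 0
    batch = max(256, n // 2)
    while remaining.sum() > 0:
        if n_candidates >= max_candidates:
            raise RuntimeError(
                "infeasible configuration: cohort quotas not fillable "
                f"after {max_candidates} candidates"
            )
        states, cls, karyo, s1, s2 = _candidate_batch(rng_geno, config, batch, loci)
        n_candidates += batch
        for i in range(batch):
            if remaining.sum() == 0:
                break
            intended = rng_assign.choice(3, p=remaining / remaining.sum())
            eligible = (
                intended == 0
                or (intended == 1 and s1[i])
                or (intended == 2 and s1[i] and s2[i])
            )
            if not eligible:
                continue
            remaining[intended] -= 1
            kept_states.append(states[i])
            kept_age.append(int(intended))
            kept_class.append(str(cls[i]))
            kept_karyo.append(int(karyo[i]) if karyo is not None else -1)
            kept_s1.append(bool(s1[i]))
            kept_s2.append(bool(s2[i]))

    ids = [f"ind{i:04d}" for i in range(n)]
    matrix = AimMatrix(np.vstack(kept_states), loci, ids)
    sex = np.where(rng_assign.random(n) < 0.5, "F", "M")
    meta_table = pd.DataFrame(
        {"age": kept_age, "sex": sex}, index=pd.Index(ids, name="individual_id")
    )
    meta = SampleMeta(meta_table).with_summaries(matrix)
    truth = SimTruth(
        selection_targets=list(config.selection_targets),
        mismatch_targets=list(config.mismatch_targets),
        inversion=config.inversion,
        inversion_genotypes=(
            np.array(kept_karyo) if config.inversion is not None else None
        ),
        ancestry_class=kept_class,
        survived_first=np.array(kept_s1),
        survived_second=np.array(kept_s2),
    )
    return matrix, meta, truth


# --------------------------------------------------------------- scenarios
#
# Named study conditions used by the validation suite.  The plain
# SimConfig() default emulates the sampled hybrid zone itself (inland-biased
# ancestry, block LD); the scenario constructors below define the cohorts
# under which each scan's statistical behaviour is checked.  See the methods
# note for the reasoning behind each choice.


def null_calibration_config(seed: int = 0, n_individuals: int = 400) -> SimConfig:
    """No-selection cohort for type-I-error calibration of the het scan.

    Uses 200 effectively unlinked AIMs (1 Mb spacing, switch rate 1/Mb) so
    the 200 per-locus tests are independent, and an inland-biased mixture
    without coastal-side classes so heterozygosity is monotone in ancestry
    over the sampled range and the logistic mean model is near-correctly
    specified; under these conditions raw p-values are uniform under the
    null.
    """
    return SimConfig(
        n_individuals=n_individuals,
        chromosomes=(("chr1", 200_000_000, 200, False),),
        ancestry_mix={"inland": 0.10, "bc_inland": 0.12, "later": 0.78},
        tract_switch_rate=1.0,
        later_concentration=10.0,
        seed=seed,
    )


RECOVERY_CHROMOSOMES = tuple(
    (f"chr{i}", 160_000_000, 80, False) for i in (1, 2, 3, 5, 7)
)
RECOVERY_HET_TARGETS = (40, 120, 200, 280, 360)  # mid-chromosome, one per chrom
RECOVERY_PAIR_TARGETS = ((40, 120), (200, 280), (60, 360))  # cross-chromosome


def _recovery_base(seed: int, n_individuals: int) -> dict:
    # balanced hybrid swarm over an unlinked 400-AIM panel: ancestry and
    # heterozygosity are uncorrelated at the cohort mean, so multi-locus
    # viability selection does not induce a genome-wide ancestry-age shift
    # that would mask the planted targets
    return dict(
        n_individuals=n_individuals,
        chromosomes=RECOVERY_CHROMOSOMES,
        ancestry_mix={"later": 1.0},
        target_mean_ancestry=0.5,
        later_concentration=2.0,
        tract_switch_rate=1.0,
        seed=seed,
    )


def selection_recovery_config(seed: int = 0, n_individuals: int = 900) -> SimConfig:
    """Cohort with five het-selected loci for scan-recovery validation.

    Selection against interspecific heterozygosity (logit-scale effect -2
    per survival transition) is planted at one mid-chromosome locus on each
    of five chromosomes.
    """
    targets = [SelectionTarget(l, -2.0) for l in RECOVERY_HET_TARGETS]
    return SimConfig(selection_targets=targets, **_recovery_base(seed, n_individuals))


def pair_recovery_config(seed: int = 0, n_individuals: int = 900) -> SimConfig:
    """Cohort with three epistatically selected cross-chromosome locus pairs.

    The survival cost of ancestry mismatch scales with genome-wide ancestry
    (coefficient -6 on mismatch x q), so the planted pairs surface on the
    ancestry-by-age interaction term of the pairwise scan.
    """
    targets = [
        MismatchTarget(i, j, 0.0, beta_pair_q=-6.0) for i, j in RECOVERY_PAIR_TARGETS
    ]
    return SimConfig(mismatch_targets=targets, **_recovery_base(seed, n_individuals))


INVERSION_INTERVAL = ("chr1", 2_000_001, 3_500_000)


def inversion_recovery_config(seed: int = 0, n_individuals: int = 300) -> SimConfig:
    """Dense single-chromosome cohort with a planted 1.5 Mb inversion.

    1,500 loci over 6 Mb (25 per 100 kb window) with short background
    tracts (switch rate 20/Mb), so only the inversion creates window-scale
    structure: 15 consecutive windows with three karyotype clusters and
    heterokaryotype heterozygosity ~1 inside the interval.
    """
    return SimConfig(
        n_individuals=n_individuals,
        chromosomes=(("chr1", 6_000_000, 1500, False),),
        ancestry_mix={"later": 1.0},
        later_concentration=2.0,
        tract_switch_rate=20.0,
        inversion=INVERSION_INTERVAL,
        seed=seed,
    )


def simulate_recomb_map(
    config: SimConfig,
    window_bp: int = 100_000,
    low_rate: float = 2.0,
    high_rate: float = 20.0,
    noise_sd: float = 0.1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Two-valued per-window recombination-rate map.

    Windows whose midpoint falls inside the configured inversion get
    ``low_rate``, all others ``high_rate``, each with multiplicative
    log-normal noise of scale ``noise_sd`` (0 disables noise).  Columns:
    chrom, start, end (1-based closed), rate, in_inversion.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if low_rate < 0 or high_rate < 0 or low_rate >= high_rate:
        raise ValueError("require 0 <= low_rate < high_rate")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    rows = []
    inv = config.inversion
    for label, length, _, _ in config.chromosomes:
        n_win = (length + window_bp - 1) // window_bp
        for w in range(n_win):
            start = w * window_bp + 1
            end = min((w + 1) * window_bp, length)
            mid = (start + end) / 2
            inside = inv is not None and inv[0] == label and inv[1] <= mid <= inv[2]
            rate = low_rate if inside else high_rate
            if noise_sd > 0:
                rate *= float(np.exp(rng.normal(0.0, noise_sd)))
            rows.append(
                {
                    "chrom": label,
                    "start": start,
                    "end": end,
                    "rate": rate,
                    "in_inversion": inside,
                }
            )
    return pd.DataFrame(rows)


def simulate_hic_pair(
    n_bins: int = 60,
    bin_bp: int = 10_000,
    intensity: float = 100.0,
    planted_interaction: tuple[int, int, float] | None = None,
    neighborhood: int = 1,
    seed: int = 0,
):
    """Toy Hi-C contact-matrix pair sharing a distance-decay expectation.

    Counts are Poisson with mean ``intensity / (1 + |i - j|)``.  When a
    ``(bin_i, bin_j, fold)`` interaction is planted, matrix A's expected
    counts in the ``(2*neighborhood+1)``-wide square around that cell (and
    its mirror) are multiplied by ``fold`` — a long-range contact present
    in one genome only.  Returns ``(A, B)``.
    """
    from hybridscan.hic import ContactMatrix

    if planted_interaction is not None:
        bi, bj, fold = planted_interaction
        if not (0 <= bi < bj < n_bins):
            raise ValueError("require 0 <= bin_i < bin_j < n_bins")
        if fold < 1:
            raise ValueError("fold must be >= 1")
    rng = np.random.default_rng(seed)
    ij = np.arange(n_bins)
    mu = intensity / (1.0 + np.abs(ij[:, None] - ij[None, :]))
    mu_a = mu.copy()
    if planted_interaction is not None:
        lo_i, hi_i = max(bi - neighborhood, 0), min(bi + neighborhood + 1, n_bins)
        lo_j, hi_j = max(bj - neighborhood, 0), min(bj + neighborhood + 1, n_bins)
        mu_a[lo_i:hi_i, lo_j:hi_j] *= fold
        mu_a[lo_j:hi_j, lo_i:hi_i] *= fold

    def draw(mean: np.ndarray) -> np.ndarray:
        upper = rng.poisson(np.triu(mean)).astype(float)
        return upper + np.triu(upper, 1).T

    a = ContactMatrix(draw(mu_a), bin_bp)
    b = ContactMatrix(draw(mu), bin_bp)
    return a, b
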