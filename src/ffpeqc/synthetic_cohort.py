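"""Synthetic study-shaped cohorts with known ground truth.

Generates everything the analysis modules consume — per-sample QC tables,
fragment-size distributions and rendered electropherogram traces, expression
matrices with replicate pairs, gene-body and GC profiles — from a latent
degradation model, so that every pipeline stage can be tested end to end
against planted truth without any external data.

Degradation is expressed through the fragment-size distribution: each sample
gets a lognormal mass-weighted size distribution whose mean declines
exponentially with (an equivalent of) storage years, and DV values are then
*computed* from that distribution by :mod:`ffpeqc.fragment_metrics` rather
than sampled directly, which guarantees DV50 >= DV100 >= DV200 by
construction. Storage-time/DV correlation targets are achieved through a
shared latent variable (latent = rho * standardized-storage + noise), and
the correlations actually achieved are measured and reported, never assumed.

Everything is driven by an integer-seeded :class:`numpy.random.Generator`;
a fixed seed reproduces the cohort bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .expression_metrics import ExpressionMatrix, GCProfile, GeneBodyProfile
from .fragment_metrics import (
    DVProfile,
    ElectropherogramTrace,
    FragmentSizeDistribution,
    dv_profile,
)
from .sample_qc import SampleQCRecord

__all__ = [
    "CohortConfig",
    "ExpressionConfig",
    "SyntheticTruth",
    "ExpressionTruth",
    "simulate_cohort",
    "render_trace",
    "simulate_expression",
    "lognormal_size_distribution",
]


@dataclass
class CohortConfig:
    """Study conditions for a synthetic QC cohort.

    Defaults emulate a 67-sample archival FFPE cohort: storage 7-32 years,
    mean fragment size declining as ``a*exp(-b*years) + c`` (a=250 nt,
    b=0.08/yr, c=40 nt), DV not computable for ~1 sample in 5, a bimodal
    contamination mixture (a near-zero clean component plus a heavy Beta
    tail), and library yield decaying with degradation under wide lognormal
    noise. ``yield_noise_sd`` defaults to sqrt(3) * ``yield_degradation_slope``
    so the storage/yield correlation comes out near its -0.2 target given the
    -0.4 storage/DV100 latent.
    """

    n_samples: int = 67
    seed: int = 0
    # storage-time structure (years), closed bins with sampling weights
    storage_bins: Tuple[Tuple[int, int], ...] = ((7, 12), (13, 22), (23, 32))
    storage_bin_probs: Tuple[float, ...] = (0.22, 0.53, 0.25)
    missing_storage_rate: float = 1.0 / 67.0
    # degradation model: mean fragment size vs years
    degradation_a_nt: float = 250.0
    degradation_b_per_yr: float = 0.08
    degradation_c_nt: float = 40.0
    size_jitter_sd: float = 0.05  # extra lognormal measurement jitter
    lognormal_shape: float = 0.9  # sigma of the per-sample size distribution
    # correlation targets (storage vs metric); the DV100 target drives the
    # shared latent, the others are reported as achieved
    target_corr_storage_dv100: float = -0.4
    target_corr_storage_dv200: float = -0.45
    target_corr_storage_yield: float = -0.2
    # missingness, mirroring marker-detection failures and unmeasurable RIN
    missing_dv_rate: float = 14.0 / 67.0
    missing_rin_rate: float = 6.0 / 67.0
    # contamination mixture
    contamination_prob: float = 0.84
    contamination_beta: Tuple[float, float] = (1.2, 2.5)
    contamination_max_pct: float = 48.0
    # library yield model (lognormal decay in the degradation latent)
    yield_median_ng: float = 25.0
    yield_degradation_slope: float = 0.8
    yield_noise_sd: float = 0.8 * math.sqrt(3.0)
    # library size / molarity
    lib_size_mean_bp: float = 405.0
    lib_size_contamination_slope: float = 2.0
    lib_size_noise_bp: float = 35.0
    # mapping model: mapped% / mRNA% rise with DV100, fall with contamination
    mapped_dv100_mid: float = 45.0
    mapped_dv100_scale: float = 12.0
    mapped_contamination_penalty: float = 0.8
    mrna_max_pct: float = 34.0
    # expression-quality tiers (concordant / intermediate / near-empty)
    tier_proportions: Tuple[float, float, float] = (0.39, 0.19, 0.42)
    n_replicate_pairs: int = 7
    resequenced_rate: float = 25.0 / 67.0
    # size grid on which distributions are evaluated
    grid_max_nt: float = 2000.0
    grid_step_nt: float = 1.0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        for name in (
            "missing_storage_rate", "missing_dv_rate", "missing_rin_rate",
            "contamination_prob", "resequenced_rate",
        ):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name}={p} outside [0, 1]")
        for t in (
            self.target_corr_storage_dv100,
            self.target_corr_storage_dv200,
            self.target_corr_storage_yield,
        ):
            if abs(t) > 1.0 or (abs(t) > 0.95 and self.size_jitter_sd > 0.01):
                # |r| near 1 is only attainable in the (near) noise-free
                # monotone limit; with measurement jitter it is infeasible
                raise ValueError(
                    f"target correlation {t} infeasible under the configured noise"
                )
        if abs(sum(self.tier_proportions) - 1.0) > 1e-9:
            raise ValueError("tier_proportions must sum to 1")
        if not abs(sum(self.storage_bin_probs) - 1.0) < 1e-9:
            raise ValueError("storage_bin_probs must sum to 1")
        if self.degradation_a_nt <= 0 or self.degradation_c_nt <= 0:
            raise ValueError("degradation sizes must be positive")
        if 2 * self.n_replicate_pairs > self.n_samples:
            raise ValueError("more replicate rows than samples")


@dataclass
class SyntheticTruth:
    """Planted ground truth for a simulated QC cohort.

    ``samples`` has one row per emitted record (latent degradation, true DV
    values before missingness, contamination state, tier, replicate pairing,
    mapped/mRNA percentages); ``achieved_correlations`` are the sample
    correlations measured on the emitted records.
    """

    samples: pd.DataFrame
    achieved_correlations: Dict[str, float] = field(default_factory=dict)


def lognormal_size_distribution(
    mean_size_nt: float,
    shape: float = 0.9,
    grid_max_nt: float = 2000.0,
    grid_step_nt: float = 1.0,
) -> FragmentSizeDistribution:
    """Lognormal mass-weighted fragment-size distribution on a regular grid.

    ``mean_size_nt`` is the mass-weighted mean fragment length; ``shape`` is
    the lognormal sigma (wider = more heterogeneous fragmentation).
    """
    if mean_size_nt <= 0 or grid_step_nt <= 0:
        raise ValueError("mean size and grid step must be positive")
    sizes = np.arange(grid_step_nt, grid_max_nt + grid_step_nt / 2, grid_step_nt)
    mu = math.log(mean_size_nt) - shape**2 / 2.0
    x = np.log(sizes)
    pdf = np.exp(-((x - mu) ** 2) / (2 * shape**2)) / (sizes * shape * math.sqrt(2 * math.pi))
    return FragmentSizeDistribution(sizes, pdf)


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 3 or np.ptp(a[ok]) == 0 or np.ptp(b[ok]) == 0:
        return float("nan")
    return float(np.corrcoef(a[ok], b[ok])[0, 1])


def simulate_cohort(
    config: Optional[CohortConfig] = None,
) -> Tuple[List[SampleQCRecord], SyntheticTruth]:
    """Simulate a QC cohort; reproducible for a fixed ``config.seed``.

    Returns validated records (DV monotonicity holds by construction since
    DV values are computed from each sample's size distribution) plus the
    planted truth. A configured fraction of samples has missing DV/RIN;
    replicate rows share storage time and site but draw independent quality
    latents, mirroring how replicate sections behave in practice.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    # storage years: replicate rows duplicate their case's year and site
    n_cases = n - config.n_replicate_pairs
    bin_idx = rng.choice(len(config.storage_bins), size=n_cases, p=config.storage_bin_probs)
    case_years = np.array(
        [rng.integers(config.storage_bins[b][0], config.storage_bins[b][1] + 1) for b in bin_idx],
        dtype=float,
    )
    case_site = rng.integers(1, 4, size=n_cases)
    years = np.concatenate([case_years, case_years[: config.n_replicate_pairs]])
    site = np.concatenate([case_site, case_site[: config.n_replicate_pairs]])
    pair_id = np.full(n, -1)
    for p in range(config.n_replicate_pairs):
        pair_id[p] = p
        pair_id[n_cases + p] = p
    order = rng.permutation(n)
    years, site, pair_id = years[order], site[order], pair_id[order]

    # shared degradation latent with the configured storage correlation
    rho = abs(config.target_corr_storage_dv100)
    s = (years - years.mean()) / max(years.std(), 1e-9)
    z = rng.standard_normal(n)
    latent = rho * s + math.sqrt(1 - rho**2) * z

    years_equiv = np.clip(years.mean() + years.std() * latent, 1.0, 60.0)
    mean_size = (
        config.degradation_a_nt * np.exp(-config.degradation_b_per_yr * years_equiv)
        + config.degradation_c_nt
    ) * np.exp(config.size_jitter_sd * rng.standard_normal(n))

    dv50 = np.empty(n)
    dv100 = np.empty(n)
    dv200 = np.empty(n)
    for i in range(n):
        dist = lognormal_size_distribution(
            mean_size[i], config.lognormal_shape, config.grid_max_nt, config.grid_step_nt
        )
        prof = dv_profile(dist)
        dv50[i], dv100[i], dv200[i] = prof.dv

    dv_missing = rng.random(n) < config.missing_dv_rate
    rin_missing = rng.random(n) < config.missing_rin_rate
    rin = np.clip(2.6 - 0.25 * latent + 0.3 * rng.standard_normal(n), 1.0, 4.0)

    contaminated = rng.random(n) < config.contamination_prob
    a_b, b_b = config.contamination_beta
    contamination = np.where(
        contaminated,
        1.0 + (config.contamination_max_pct - 1.0) * rng.beta(a_b, b_b, size=n),
        rng.uniform(0.0, 1.0, size=n),
    )

    log_yield = (
        math.log(config.yield_median_ng)
        - config.yield_degradation_slope * latent
        + config.yield_noise_sd * rng.standard_normal(n)
    )
    lib_yield = np.maximum(np.exp(log_yield), 0.5)

    lib_size = np.maximum(
        config.lib_size_mean_bp
        + config.lib_size_contamination_slope * (contamination - contamination.mean())
        + config.lib_size_noise_bp * rng.standard_normal(n),
        150.0,
    )
    lib_molarity = np.maximum(
        lib_yield / 3.4 * (config.lib_size_mean_bp / lib_size)
        * np.exp(0.1 * rng.standard_normal(n)),
        0.05,
    )

    def sigmoid(x):
        return 1.0 / (1.0 + np.exp(-x))

    mapped = np.clip(
        100.0 * sigmoid((dv100 - config.mapped_dv100_mid) / config.mapped_dv100_scale)
        - config.mapped_contamination_penalty * contamination,
        1.0,
        95.0,
    )
    mrna = np.clip(
        config.mrna_max_pct
        * sigmoid((dv100 - 50.0) / 15.0)
        * (1.0 - contamination / 100.0)
        + 1.5 * rng.standard_normal(n),
        0.5,
        config.mrna_max_pct,
    )

    # expression-quality tiers from a noisy mapping-quality score
    props = np.array(config.tier_proportions)
    counts = np.floor(props * n).astype(int)
    for k in np.argsort(-(props * n - counts)):
        if counts.sum() >= n:
            break
        counts[k] += 1
    score = mapped + 10.0 * rng.standard_normal(n)
    tier = np.empty(n, dtype="U1")
    ranks = np.argsort(-score)
    tier[ranks[: counts[0]]] = "B"
    tier[ranks[counts[0]: counts[0] + counts[1]]] = "C"
    tier[ranks[counts[0] + counts[1]:]] = "D"

    genes_mu = {"B": math.log(16000), "C": math.log(9000), "D": math.log(300)}
    genes_sd = {"B": 0.35, "C": 0.8, "D": 2.0}
    genes = np.array(
        [
            int(np.clip(np.exp(rng.normal(genes_mu[t], genes_sd[t])), 0, 40000))
            for t in tier
        ]
    )

    input_amt = np.where(
        rng.random(n) < 0.55, 1000.0, rng.uniform(90.0, 1030.0, size=n)
    )
    resequenced = rng.random(n) < config.resequenced_rate
    storage_missing = rng.random(n) < config.missing_storage_rate

    records: List[SampleQCRecord] = []
    for i in range(n):
        rec = SampleQCRecord(
            sample_id=f"SYN_{i + 1:03d}",
            input_for_libprep=round(float(input_amt[i]), 1),
            rin=None if rin_missing[i] else round(float(rin[i]), 1),
            dv200=None if dv_missing[i] else round(float(dv200[i]), 1),
            dv100=None if dv_missing[i] else round(float(dv100[i]), 1),
            dv50=None if dv_missing[i] else round(float(dv50[i]), 1),
            lib_size=round(float(lib_size[i])),
            lib_yield=round(float(lib_yield[i]), 2),
            lib_molarity=round(float(lib_molarity[i]), 3),
            storage_time=None if storage_missing[i] else int(years[i]),
            resequenced=bool(resequenced[i]),
            contamination_pct=round(float(contamination[i]), 2),
            cluster_label=str(tier[i]),
            genes_detected=int(genes[i]),
            site=f"site{site[i]}",
        )
        problems = rec.validate()
        if problems:  # pragma: no cover - generator invariant
            raise AssertionError(f"generator emitted invalid record: {problems}")
        records.append(rec)

    truth_df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "storage_years": years,
            "storage_missing": storage_missing,
            "latent_degradation": latent,
            "mean_fragment_size_nt": mean_size,
            "dv50_true": dv50,
            "dv100_true": dv100,
            "dv200_true": dv200,
            "dv_missing": dv_missing,
            "contaminated": contaminated,
            "contamination_pct": contamination,
            "tier": tier,
            "mapped_pct": mapped,
            "mrna_pct": mrna,
            "replicate_pair": pair_id,
            "site": [f"site{x}" for x in site],
        }
    )

    obs_years = np.where(storage_missing, np.nan, years)
    obs_dv100 = np.where(dv_missing, np.nan, dv100)
    obs_dv200 = np.where(dv_missing, np.nan, dv200)
    achieved = {
        "storage_dv100": _corr(obs_years, obs_dv100),
        "storage_dv200": _corr(obs_years, obs_dv200),
        "storage_lib_yield": _corr(obs_years, lib_yield),
        "dv100_mapped": _corr(obs_dv100, mapped),
        "contamination_mapped": _corr(contamination, mapped),
    }
    return records, SyntheticTruth(samples=truth_df, achieved_correlations=achieved)


def render_trace(
    dist: FragmentSizeDistribution,
    noise_sd: float = 0.0,
    marker: bool = True,
    grid_step_nt: float = 1.0,
    *,
    size_range: Tuple[float, float] = (1.0, 4000.0),
    baseline_offset: float = 0.05,
    marker_nt: float = 25.0,
    marker_sd_nt: float = 1.0,
    marker_height_rel: float = 3.0,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[ElectropherogramTrace, DVProfile]:
    """Render a distribution to an instrument-style trace.

    The trace is the distribution's mass density sampled on a regular grid,
    plus (optionally) a narrow Gaussian lower-marker peak at ``marker_nt``,
    a constant non-negative baseline offset, and additive Gaussian noise
    (``noise_sd`` relative to the density maximum). Returns the trace
    together with the ground-truth DV profile of the generating
    distribution.
    """
    if grid_step_nt <= 0:
        raise ValueError("grid step must be positive")
    rng = rng or np.random.default_rng(0)
    lo, hi = size_range
    grid = np.arange(lo, hi + grid_step_nt / 2, grid_step_nt)
    density = np.interp(grid, dist.sizes, dist.mass_weights, left=0.0, right=0.0)
    peak = density.max()
    if peak > 0:
        density = density / peak
    signal = density.copy()
    if marker:
        signal = signal + marker_height_rel * np.exp(
            -((grid - marker_nt) ** 2) / (2 * marker_sd_nt**2)
        )
    signal = signal + baseline_offset
    if noise_sd > 0:
        signal = signal + noise_sd * rng.standard_normal(grid.size)
    return ElectropherogramTrace(grid, signal, lower_marker_nt=marker_nt), dv_profile(dist)


@dataclass
class ExpressionConfig:
    """Conditions for a synthetic expression cohort.

    Quality tiers mirror the concordance classes seen in archival FFPE
    expression data: tier B tracks the reference signature pattern, tier C
    shows attenuated signature expression with a shared tier-specific
    distortion, tier D has almost no signature reads (and globally shallow
    libraries). Concordant replicate pairs share a latent expression
    component sized so that their log-scale correlation equals
    ``concordant_r``; discordant pairs couple a tier-B member with a
    near-noise tier-D member.
    """

    n_samples: int = 20
    n_genes: int = 2000
    n_signature: int = 193
    seed: int = 0
    tier_proportions: Tuple[float, float, float] = (0.39, 0.19, 0.42)
    concordant_pairs: int = 0
    discordant_pairs: int = 0
    concordant_r: float = 0.75
    # expression scales (log2 TPM-like units)
    base_log2_mean: float = 4.0
    base_log2_sd: float = 2.0
    bio_sd: float = 2.0
    sig_noise_sd_b: float = 0.8
    tier_pattern_sd: float = 1.6  # shared within-tier signature distortion
    sig_kappa_c: float = 0.5
    sig_shift_c: float = -2.0
    sig_shift_d: float = -7.0
    global_kappa_d: float = 0.2
    global_shift_d: float = -1.0
    global_extra_sd_d: float = 2.0
    # sequencing depths (expected aligned reads per sample)
    depth_bc: float = 3.0e6
    depth_d: float = 1.0e4
    # diagnostics profiles
    gc_anomaly_rate: float = 0.15
    mrna_ranges: Tuple[Tuple[float, float], ...] = ((10.0, 34.0), (4.0, 15.0), (0.5, 5.0))

    def validate(self) -> None:
        if abs(sum(self.tier_proportions) - 1.0) > 1e-9:
            raise ValueError("tier_proportions must sum to 1")
        if not 0 < self.concordant_r < 1:
            raise ValueError("concordant_r must be in (0, 1)")
        need = 2 * (self.concordant_pairs + self.discordant_pairs)
        if need > self.n_samples:
            raise ValueError("more replicate members than samples")
        if self.n_signature >= self.n_genes:
            raise ValueError("signature must be a strict subset of genes")
        v = self.base_log2_sd**2
        s2 = self.bio_sd**2
        rho = (self.concordant_r * (v + s2) - v) / s2
        if not 0 <= rho <= 1:
            raise ValueError(
                f"concordant_r={self.concordant_r} infeasible for "
                f"base_log2_sd={self.base_log2_sd}, bio_sd={self.bio_sd}"
            )


@dataclass
class ExpressionTruth:
    """Planted truth for a synthetic expression cohort."""

    samples: pd.DataFrame
    signature_genes: List[str]
    reference_log2tpm: np.ndarray  # aligned to signature_genes
    pairs_concordant: List[Tuple[str, str]]
    pairs_discordant: List[Tuple[str, str]]


def _assign_tiers(cfg: ExpressionConfig, rng: np.random.Generator) -> List[str]:
    n = cfg.n_samples
    props = np.array(cfg.tier_proportions)
    counts = np.floor(props * n).astype(int)
    for k in np.argsort(-(props * n - counts)):
        if counts.sum() >= n:
            break
        counts[k] += 1
    tiers = []
    # replicate-pair slots first: concordant pairs are tier B twins,
    # discordant pairs couple B with D
    for _ in range(cfg.concordant_pairs):
        tiers += ["B", "B"]
    for _ in range(cfg.discordant_pairs):
        tiers += ["B", "D"]
    remaining = {t: int(c) for t, c in zip("BCD", counts)}
    for t in tiers:
        if remaining[t] > 0:
            remaining[t] -= 1
    filler = [t for t, c in remaining.items() for _ in range(c)]
    filler = filler[: n - len(tiers)]
    while len(tiers) + len(filler) < n:
        filler.append("C")
    filler = list(rng.permutation(filler))
    return tiers + filler


def simulate_expression(
    config: Optional[ExpressionConfig] = None,
) -> Tuple[ExpressionMatrix, Dict[str, list], ExpressionTruth]:
    """Simulate counts + TPM, gene-body and GC profiles, with planted truth.

    Counts are Poisson draws around tier- and pair-structured log-normal
    expression; TPM is computed consistently from the emitted counts and the
    configured gene lengths. Gene-body profiles carry a 3' coverage ramp
    whose strength grows as mRNA content falls below 10%; GC profiles are
    centred near 50% GC with low/high-GC anomalies planted in a configured
    fraction of samples.

    Returns ``(matrix, profiles, truth)`` where ``profiles`` has keys
    ``"gene_body"`` and ``"gc"``.
    """
    cfg = config or ExpressionConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, g = cfg.n_samples, cfg.n_genes

    gene_ids = [f"GENE_{i + 1:05d}" for i in range(g)]
    sample_ids = [f"EXPR_{j + 1:03d}" for j in range(n)]
    lengths = np.exp(rng.normal(math.log(1500), 0.4, size=g))
    sig_rows = np.sort(rng.choice(g, size=cfg.n_signature, replace=False))
    is_sig = np.zeros(g, dtype=bool)
    is_sig[sig_rows] = True
    signature_genes = [gene_ids[i] for i in sig_rows]

    tiers = _assign_tiers(cfg, rng)
    mu0 = cfg.base_log2_mean
    lmu = rng.normal(mu0, cfg.base_log2_sd, size=g)  # cohort-wide gene pattern
    pattern_b = rng.normal(0.0, cfg.tier_pattern_sd, size=cfg.n_signature) * 0.5
    pattern_c = rng.normal(0.0, cfg.tier_pattern_sd, size=cfg.n_signature)

    v = cfg.base_log2_sd**2
    s2 = cfg.bio_sd**2
    rho = (cfg.concordant_r * (v + s2) - v) / s2  # pair-shared noise fraction

    pairs_concordant = [
        (sample_ids[2 * p], sample_ids[2 * p + 1]) for p in range(cfg.concordant_pairs)
    ]
    off = 2 * cfg.concordant_pairs
    pairs_discordant = [
        (sample_ids[off + 2 * p], sample_ids[off + 2 * p + 1])
        for p in range(cfg.discordant_pairs)
    ]
    shared_noise = {p: rng.standard_normal(g) for p in range(cfg.concordant_pairs)}

    x = np.empty((g, n))
    for j in range(n):
        t = tiers[j]
        w = rng.standard_normal(g)
        if j < off and j // 2 in shared_noise:
            eta = math.sqrt(rho) * shared_noise[j // 2] + math.sqrt(1 - rho) * w
        else:
            eta = w
        col = lmu + cfg.bio_sd * eta
        if t == "B":
            col = col.copy()
            col[sig_rows] = (
                lmu[sig_rows]
                + pattern_b
                + cfg.sig_noise_sd_b * rng.standard_normal(cfg.n_signature)
            )
            if j < off and j // 2 in shared_noise:
                # keep the pair-shared structure on signature genes too
                col[sig_rows] += cfg.bio_sd * 0.3 * (
                    math.sqrt(rho) * shared_noise[j // 2][sig_rows]
                    + math.sqrt(1 - rho) * w[sig_rows]
                )
        elif t == "C":
            col = col.copy()
            col[sig_rows] = (
                mu0
                + cfg.sig_kappa_c * (lmu[sig_rows] - mu0)
                + pattern_c
                + cfg.sig_shift_c
                + 0.5 * rng.standard_normal(cfg.n_signature)
            )
        else:  # tier D: globally flattened, noisy, near-zero signature
            col = (
                mu0
                + cfg.global_kappa_d * (lmu - mu0)
                + cfg.global_shift_d
                + cfg.global_extra_sd_d * rng.standard_normal(g)
            )
            col[sig_rows] = cfg.sig_shift_d + mu0 + 1.0 * rng.standard_normal(
                cfg.n_signature
            )
        x[:, j] = col

    tpm_model = np.exp2(x)
    tpm_model = tpm_model / tpm_model.sum(axis=0, keepdims=True) * 1e6
    depth = np.array([cfg.depth_d if t == "D" else cfg.depth_bc for t in tiers])
    lam = tpm_model / 1e6 * depth[None, :] * (lengths[:, None] / 1500.0)
    counts = rng.poisson(lam)
    matrix = ExpressionMatrix.from_counts(gene_ids, sample_ids, counts, lengths)

    ref_tpm = np.exp2(lmu)
    ref_tpm = ref_tpm / ref_tpm.sum() * 1e6
    reference_log2tpm = np.log2(ref_tpm[sig_rows] + 1.0)

    # diagnostics profiles
    mrna_range = dict(zip("BCD", cfg.mrna_ranges))
    positions = np.arange(100)
    gene_body: List[GeneBodyProfile] = []
    gc: List[GCProfile] = []
    mrna_pct = np.empty(n)
    planted_bias = np.zeros(n, dtype=bool)
    planted_gc = np.zeros(n, dtype=bool)
    centers = np.arange(100) + 0.5
    for j in range(n):
        lo, hi = mrna_range[tiers[j]]
        mrna_pct[j] = rng.uniform(lo, hi)
        amp = 2.5 * max(0.0, (10.0 - mrna_pct[j]) / 10.0)
        curve = 1.0 + amp * np.exp((positions - 99) / 25.0)
        curve = np.maximum(curve + 0.02 * rng.standard_normal(100), 0.0)
        planted_bias[j] = amp > 0.5
        gene_body.append(GeneBodyProfile(sample_ids[j], curve, float(mrna_pct[j])))

        reads = 1e5 * np.exp(-((centers - rng.normal(50, 2)) ** 2) / (2 * 8.0**2))
        if rng.random() < cfg.gc_anomaly_rate:
            planted_gc[j] = True
            frac = rng.uniform(0.10, 0.25)
            side = rng.integers(0, 3)  # 0 low, 1 high, 2 both
            extra = np.zeros(100)
            if side in (0, 2):
                extra += np.exp(-((centers - 5.0) ** 2) / (2 * 2.0**2))
            if side in (1, 2):
                extra += np.exp(-((centers - 85.0) ** 2) / (2 * 2.0**2))
            reads = reads + extra / extra.sum() * reads.sum() * frac / (1 - frac)
        gc.append(GCProfile(sample_ids[j], reads))

    pair_type = ["" for _ in range(n)]
    pair_label = ["" for _ in range(n)]
    for a, b in pairs_concordant:
        for sid in (a, b):
            pair_type[sample_ids.index(sid)] = "concordant"
            pair_label[sample_ids.index(sid)] = f"{a}|{b}"
    for a, b in pairs_discordant:
        for sid in (a, b):
            pair_type[sample_ids.index(sid)] = "discordant"
            pair_label[sample_ids.index(sid)] = f"{a}|{b}"

    truth = ExpressionTruth(
        samples=pd.DataFrame(
            {
                "sample_id": sample_ids,
                "tier": tiers,
                "mrna_pct": mrna_pct,
                "planted_3prime_bias": planted_bias,
                "planted_gc_anomaly": planted_gc,
                "pair_type": pair_type,
                "pair": pair_label,
            }
        ),
        signature_genes=signature_genes,
        reference_log2tpm=reference_log2tpm,
        pairs_concordant=pairs_concordant,
        pairs_discordant=pairs_discordant,
    )
    return matrix, {"gene_body": gene_body, "gc": gc}, truth
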