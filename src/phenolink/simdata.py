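"""Synthetic longitudinal cohorts with planted ground truth.

The generator emulates the statistical structure the analysis assumes: two
treatment arms (control / low-dose antibiotic) sampled repeatedly over weeks,
an all-animals diet switch from normal chow to high-fat diet, sparse
overdispersed OTU counts, subject-level random effects, a small planted set
of OTU-phenotype associations, a planted sparse inverse covariance among
OTUs, and age-graded taxa.

Counts follow a logistic-normal multinomial: latent log-abundances are
baseline + subject effect + treatment effect + diet effect + age trend +
correlated Gaussian noise with covariance inverse(precision); the sample's
library size is lognormal and counts are a multinomial draw from the
softmax-composed latents. This matches the log-ratio Gaussian structure the
clr-based inference downstream assumes, which keeps parameter-recovery tests
well-posed. Phenotypes are linear in the latent abundances of the associated
OTUs plus a subject effect and noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cholesky, solve_triangular

from .io import OtuTable, PHENOTYPES, SampleFrame
import pandas as pd


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort. Defaults define the study conditions."""

    n_subjects_per_arm: int = 20
    weeks: tuple = (4, 11, 16, 30)
    diet_switch_week: int = 13
    n_otus: int = 200
    n_assoc_otus: int = 10
    assoc_effect_size: float = 1.0
    subject_sd: float = 1.0
    depth_lognormal: tuple = (9.6, 0.3)   # ln-scale mean/sd of library size (~15k reads)
    precision_topology: str = "chain"     # chain | hub | erdos_renyi
    precision_strength: float = 0.4
    condition_target: float | None = None
    n_age_taxa: int = 20
    age_slope: float = 0.1                # log-abundance units per week on age taxa
    baseline_sd: float = 2.0
    treatment_sd: float = 0.3
    diet_sd: float = 0.5
    pheno_subject_sd: float = 1.0
    pheno_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_assoc_otus > self.n_otus:
            raise ValueError("n_assoc_otus must not exceed n_otus")
        if self.n_age_taxa + self.n_assoc_otus > self.n_otus:
            raise ValueError("planted taxa exceed n_otus")
        for name in ("subject_sd", "baseline_sd", "pheno_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(v <= 0 for v in self.depth_lognormal):
            raise ValueError("depth parameters must be positive")
        wk = list(self.weeks)
        if wk != sorted(set(wk)):
            raise ValueError("weeks must be strictly increasing")


@dataclass
class SimTruth:
    """Planted structure for downstream recovery testing."""

    true_support: np.ndarray       # boolean OTU x phenotype
    true_precision: np.ndarray     # symmetric positive-definite OTU x OTU
    true_age_taxa: dict            # OTU index -> signed slope
    true_coefficients: np.ndarray  # real OTU x phenotype

    def __post_init__(self) -> None:
        P = self.true_precision
        if not np.allclose(P, P.T):
            raise ValueError("precision must be symmetric")
        if np.linalg.eigvalsh(P).min() <= 0:
            raise ValueError("precision must be positive definite")
        if not np.array_equal(self.true_support, self.true_coefficients != 0):
            raise ValueError("support must equal the nonzero coefficient pattern")

    @property
    def assoc_otus(self) -> np.ndarray:
        return np.where(self.true_support.any(axis=1))[0]


# ---------------------------------------------------------------------------
# Precision matrices
# ---------------------------------------------------------------------------

def make_precision(p: int, topology: str = "chain", strength: float = 0.4,
                   condition_target: float | None = None,
                   seed: int | None = 0, edge_prob: float = 0.02) -> np.ndarray:
    """Sparse symmetric positive-definite precision with a known edge pattern.

    ``chain`` links consecutive OTUs (partial correlation = ``strength``),
    ``hub`` links node 0 to everything, ``erdos_renyi`` draws random edges
    and regularises the diagonal to positive definiteness.
    """
    P = np.eye(p)
    if topology == "chain":
        for i in range(p - 1):
            P[i, i + 1] = P[i + 1, i] = -strength
    elif topology == "hub":
        s = min(strength, 0.9) / np.sqrt(p - 1)
        P[0, 1:] = P[1:, 0] = -s
    elif topology == "erdos_renyi":
        rng = np.random.default_rng(seed)
        iu = np.triu_indices(p, k=1)
        mask = rng.random(len(iu[0])) < edge_prob
        vals = rng.choice([-strength, strength], size=mask.sum())
        P[iu[0][mask], iu[1][mask]] = vals
        P[iu[1][mask], iu[0][mask]] = vals
    else:
        raise ValueError(f"unknown topology {topology!r}")
    ev = np.linalg.eigvalsh(P)
    if ev.min() <= 1e-8:
        P += (abs(ev.min()) + 0.1) * np.eye(p)
        ev = np.linalg.eigvalsh(P)
    if condition_target is not None and ev.max() / ev.min() > condition_target:
        # shift the spectrum until cond(P) meets the target
        tau = (ev.max() - condition_target * ev.min()) / (condition_target - 1)
        P += tau * np.eye(p)
    return P


def _mvn_from_precision(P: np.ndarray, n: int, rng) -> np.ndarray:
    """Draw n rows of N(0, inv(P)) via the Cholesky factor of P."""
    try:
        L = cholesky(P, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError("precision matrix is singular or not PD") from exc
    z = rng.standard_normal((n, P.shape[0]))
    return solve_triangular(L, z.T, lower=True, trans="T").T


def _counts_from_latent(Z: np.ndarray, depth_lognormal: tuple, rng) -> np.ndarray:
    mu, sigma = depth_lognormal
    depths = np.maximum(rng.lognormal(mu, sigma, size=Z.shape[0]), 10).astype(int)
    comp = np.exp(Z - Z.max(axis=1, keepdims=True))
    comp /= comp.sum(axis=1, keepdims=True)
    counts = np.empty(Z.shape, dtype=np.int64)
    for i in range(Z.shape[0]):
        counts[i] = rng.multinomial(depths[i], comp[i])
    return counts


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig) -> tuple[OtuTable, SampleFrame, SimTruth]:
    """Generate a two-arm longitudinal cohort with planted associations.

    Deterministic given ``config.seed``; the returned :class:`SimTruth`
    records the planted phenotype support/coefficients, the precision matrix
    behind the correlated OTU noise, and the age-graded taxa.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    p, q = cfg.n_otus, len(PHENOTYPES)
    weeks = list(cfg.weeks)
    n_subj = 2 * cfg.n_subjects_per_arm
    subjects = [f"S{i:03d}" for i in range(n_subj)]
    treatment = ["control"] * cfg.n_subjects_per_arm + ["STAT"] * cfg.n_subjects_per_arm
    sex = [("M", "F")[i % 2] for i in range(n_subj)]

    baseline = rng.normal(0.0, cfg.baseline_sd, p)
    # planted structure: associated and age-graded taxa are disjoint, and drawn
    # from the upper half of baseline abundance so the planted signal survives
    # sequencing (rare taxa would be unobservable after count quantisation,
    # which is why the analysis prevalence-filters in the first place)
    eligible = np.where(baseline >= np.median(baseline))[0]
    n_planted = cfg.n_assoc_otus + cfg.n_age_taxa
    if n_planted > len(eligible):
        eligible = np.arange(p)
    planted = rng.choice(eligible, size=n_planted, replace=False)
    assoc_idx = planted[:cfg.n_assoc_otus]
    age_idx = planted[cfg.n_assoc_otus:]
    coef = np.zeros((p, q))
    for o in assoc_idx:
        targets = rng.choice(q, size=rng.integers(1, 4), replace=False)
        coef[o, targets] = rng.choice([-1.0, 1.0], size=len(targets)) * cfg.assoc_effect_size
    age_slopes = rng.choice([-1.0, 1.0], size=cfg.n_age_taxa) * cfg.age_slope
    precision = make_precision(p, cfg.precision_topology, cfg.precision_strength,
                               cfg.condition_target, seed=cfg.seed)

    subj_eff = rng.normal(0.0, cfg.subject_sd, (n_subj, p))
    treat_eff = rng.normal(0.0, cfg.treatment_sd, p)
    diet_eff = rng.normal(0.0, cfg.diet_sd, p)
    pheno_subj = rng.normal(0.0, cfg.pheno_subject_sd, (n_subj, q))

    rows, meta_rows, sample_ids = [], [], []
    mid_week = np.mean(weeks)
    for si, s in enumerate(subjects):
        for w in weeks:
            hfd = w >= cfg.diet_switch_week
            z = baseline + subj_eff[si] + (treat_eff if treatment[si] == "STAT" else 0)
            z = z + (diet_eff if hfd else 0)
            z = z.copy()
            z[age_idx] += age_slopes * (w - mid_week)
            rows.append(z)
            sample_ids.append(f"{s}.w{w}")
            meta_rows.append({"subject_id": s, "week": w,
                              "treatment": treatment[si],
                              "diet": "HFD" if hfd else "NC", "sex": sex[si]})
    Z = np.asarray(rows) + _mvn_from_precision(precision, len(rows), rng)
    counts = _counts_from_latent(Z, cfg.depth_lognormal, rng)

    Y = Z @ coef
    for i, m in enumerate(meta_rows):
        si = subjects.index(m["subject_id"])
        Y[i] += pheno_subj[si]
    Y += rng.normal(0.0, cfg.pheno_noise_sd, Y.shape)

    # fasting labs for the HOMA-IR stage: lognormal, loosely tied to adiposity
    glucose = rng.lognormal(np.log(180.0), 0.2, len(rows))
    insulin = rng.lognormal(np.log(15.0), 0.4, len(rows))

    taxonomy = [f"k__Bacteria;p__Phylum{j % 5};g__g{j}" for j in range(p)]
    table = OtuTable(counts, sample_ids, [f"OTU{j:04d}" for j in range(p)], taxonomy)
    meta = pd.DataFrame(meta_rows, index=sample_ids)
    for r, name in enumerate(PHENOTYPES):
        meta[name] = Y[:, r]
    meta["glucose"] = glucose
    meta["insulin"] = insulin
    truth = SimTruth(coef != 0, precision, dict(zip(age_idx.tolist(), age_slopes)),
                     coef)
    return table, SampleFrame(meta), truth


def simulate_network_counts(precision: np.ndarray, n_samples: int,
                            depth: tuple = (9.6, 0.3), seed: int | None = 0,
                            baseline_sd: float = 1.0) -> OtuTable:
    """Logistic-normal multinomial counts whose latent covariance is inv(precision)."""
    precision = np.asarray(precision, dtype=float)
    if not np.allclose(precision, precision.T):
        raise ValueError("precision must be symmetric")
    rng = np.random.default_rng(seed)
    p = precision.shape[0]
    baseline = rng.normal(0.0, baseline_sd, p)
    Z = baseline + _mvn_from_precision(precision, n_samples, rng)
    counts = _counts_from_latent(Z, depth, rng)
    return OtuTable(counts, [f"N{i:04d}" for i in range(n_samples)],
                    [f"OTU{j:04d}" for j in range(p)])


def simulate_age_series(config: SimConfig, n_samples: int = 150,
                        ages: np.ndarray | None = None,
                        maturation_rate: float = 1.0,
                        seed: int | None = None,
                        sample_prefix: str = "A") -> tuple[OtuTable, np.ndarray]:
    """Cross-sectional series with monotone log-linear trends on the age taxa.

    The planted structure (which taxa, their signed slopes, baselines) is
    drawn from ``config.seed``, so series sharing a config share their age
    taxa; ``seed`` controls only the sampling noise, letting independent arms
    be drawn against the same maturation program. ``maturation_rate`` < 1
    emulates delayed development: a sample at nominal age a carries the
    composition of effective age ``a_min + rate * (a - a_min)``. Non-age taxa
    are exchangeable noise around their baselines.
    """
    import warnings
    cfg = config
    if cfg.n_age_taxa == 0:
        warnings.warn("n_age_taxa = 0: age is unlearnable from this series",
                      stacklevel=2)
    struct_rng = np.random.default_rng(cfg.seed)
    p = cfg.n_otus
    age_idx = struct_rng.choice(p, size=cfg.n_age_taxa, replace=False)
    slopes = struct_rng.choice([-1.0, 1.0], size=cfg.n_age_taxa) * cfg.age_slope
    baseline = struct_rng.normal(0.0, cfg.baseline_sd, p)

    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    lo, hi = cfg.weeks[0], cfg.weeks[-1]
    if ages is None:
        ages = np.sort(rng.uniform(lo, hi, n_samples))
    ages = np.asarray(ages, dtype=float)
    eff = lo + maturation_rate * (ages - lo)
    Z = np.tile(baseline, (len(ages), 1))
    Z[:, age_idx] += np.outer(eff - (lo + hi) / 2, slopes)
    Z += rng.standard_normal(Z.shape)
    counts = _counts_from_latent(Z, cfg.depth_lognormal, rng)
    table = OtuTable(counts, [f"{sample_prefix}{i:04d}" for i in range(len(ages))],
                     [f"OTU{j:04d}" for j in range(p)])
    return table, ages


def simulate_score_clusters(k: int = 6, n_per: int = 70, d: int = 7,
                            sep: float = 8.0, anisotropy: float = 0.8,
                            seed: int | None = 0) -> tuple[np.ndarray, np.ndarray]:
    """Planted ellipsoidal clusters in latent-score space.

    Emulates the geometry of sPLS sample scores when the cohort occupies a
    small number of phenotype states: ``k`` well-separated Gaussian clusters
    in ``d`` dimensions with distinct full covariances. Returns (scores,
    labels) for clustering-recovery tests.
    """
    rng = np.random.default_rng(seed)
    means = rng.normal(0.0, sep, (k, d))
    X, labels = [], []
    for j in range(k):
        A = rng.normal(0.0, 1.0, (d, d)) * anisotropy
        cov = A @ A.T + np.eye(d) * 0.2
        X.append(rng.multivariate_normal(means[j], cov, n_per))
        labels += [j] * n_per
    return np.vstack(X), np.asarray(labels)


def simulate_disease_cohort(n_per_group: int = 20, weeks=(4, 11, 16, 30),
                            n_otus: int = 100, n_marker: int = 10,
                            effect: float = 1.5, baseline_sd: float = 1.5,
                            depth_lognormal: tuple = (9.6, 0.3),
                            seed: int | None = 0):
    """Two outcome groups with planted discriminative taxa at every week.

    Diseased animals carry a signed log-abundance shift of size ``effect`` on
    ``n_marker`` marker OTUs (drawn from the upper half of baseline
    abundance); everything else is exchangeable. Returns
    ``(table, labels, week_of_sample, marker_idx)``.
    """
    rng = np.random.default_rng(seed)
    baseline = rng.normal(0.0, baseline_sd, n_otus)
    eligible = np.where(baseline >= np.median(baseline))[0]
    marker = rng.choice(eligible, size=n_marker, replace=False)
    shift = rng.choice([-1.0, 1.0], size=n_marker) * effect
    rows, labels, wk, ids = [], [], [], []
    for g, lab in enumerate(("healthy", "disease")):
        for s in range(n_per_group):
            for w in weeks:
                z = baseline + rng.standard_normal(n_otus)
                if lab == "disease":
                    z = z.copy()
                    z[marker] += shift
                rows.append(z)
                labels.append(lab)
                wk.append(w)
                ids.append(f"D{g}{s:02d}.w{w}")
    counts = _counts_from_latent(np.asarray(rows), depth_lognormal, rng)
    table = OtuTable(counts, ids, [f"OTU{j:04d}" for j in range(n_otus)])
    return table, np.asarray(labels), np.asarray(wk), marker


def null_config(config: SimConfig | None = None, **overrides) -> SimConfig:
    """A copy of the config with every planted phenotype effect removed."""
    cfg = config or SimConfig()
    return replace(cfg, n_assoc_otus=0, **overrides)
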