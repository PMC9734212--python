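"""Random-effects multinomial baseline-category logit for bee choice data.

Each of the four experimental conditions (tested parameter x trained
level) is analysed with a baseline-category logit: the log odds of
choosing stimulus level k in {2, 3, 4} relative to level 1 (the
baseline) is

    eta_k = beta0_k + beta1_k * species + u,      u ~ Normal(0, sigma^2),

where ``species`` is an indicator for the second species and ``u`` is a
per-individual random intercept shared across the three category logits,
imposing a correlation structure on all choices made by one bee.  The
marginal likelihood integrates ``u`` out by Gauss-Hermite quadrature
with a fixed node count, so fits are deterministic.  The species effect
is tested with a likelihood-ratio test on its three terms (df = 3).

Data schema (long form, one row per recorded choice):
``bee_id, species, parameter, trained_level, training_round,
choice_rank, chosen_level``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

__all__ = [
    "CHOICE_COLUMNS",
    "N_LEVELS",
    "ChoiceDataset",
    "CategoryLogitFit",
    "LogOddsRow",
    "LRTResult",
    "read_choices",
    "read_choices_xlsx",
    "write_choices",
    "filter_primary",
    "fit_model",
    "log_odds_table",
    "log_odds_frame",
    "lrt_species",
    "predicted_proportions",
]

CHOICE_COLUMNS = ["bee_id", "species", "parameter", "trained_level",
                  "training_round", "choice_rank", "chosen_level"]
N_LEVELS = 4


@dataclass(frozen=True)
class ChoiceDataset:
    """Long-form bee choice records with provenance."""

    records: pd.DataFrame
    provenance: str = ""

    def __post_init__(self):
        df = self.records
        missing = [c for c in CHOICE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"choice data missing columns: {missing}")
        lev = df["chosen_level"].to_numpy()
        if len(df) and (lev.min() < 1 or lev.max() > N_LEVELS):
            raise ValueError(f"chosen_level must be in 1..{N_LEVELS}")
        if len(df) and df["choice_rank"].min() < 1:
            raise ValueError("choice_rank must be >= 1")

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, parameter: str | None = None,
               trained_level: str | None = None) -> "ChoiceDataset":
        df = self.records
        if parameter is not None:
            df = df[df["parameter"] == parameter]
        if trained_level is not None:
            df = df[df["trained_level"] == trained_level]
        return replace(self, records=df.reset_index(drop=True))

    @property
    def species_levels(self) -> list[str]:
        return sorted(self.records["species"].unique())


def read_choices(path, provenance: str | None = None) -> ChoiceDataset:
    """Read choice records from delimited text (separator sniffed)."""
    df = pd.read_csv(path, sep=None, engine="python")
    return ChoiceDataset(df, provenance or str(path))


def read_choices_xlsx(path, sheet: int | str | None = None,
                      column_map: dict | None = None) -> ChoiceDataset:
    """Import choice records from a spreadsheet workbook.

    ``column_map`` renames workbook headers onto the package schema; when
    ``sheet`` is None all sheets are concatenated.
    """
    sheets = pd.read_excel(path, sheet_name=sheet)
    if isinstance(sheets, dict):
        df = pd.concat(sheets.values(), ignore_index=True)
    else:
        df = sheets
    if column_map:
        df = df.rename(columns=column_map)
    return ChoiceDataset(df[CHOICE_COLUMNS].copy(), provenance=str(path))


def write_choices(dataset: ChoiceDataset, path) -> None:
    dataset.records.to_csv(path, index=False)


def filter_primary(dataset: ChoiceDataset) -> ChoiceDataset:
    """Keep only each bee's first training round and first five choices.

    Restricting to the first conditioning experienced avoids
    pseudo-replication from the reverse-training round, and only the
    first five unrewarded test choices per bee are evaluated.
    """
    df = dataset.records
    df = df[(df["training_round"] == 1) & (df["choice_rank"] <= 5)]
    return replace(dataset, records=df.reset_index(drop=True),
                   provenance=dataset.provenance + " | round1,first5")


# ---------------------------------------------------------------------------
# Fitting


@dataclass(frozen=True)
class CategoryLogitFit:
    """A fitted baseline-category logit with a shared random intercept.

    ``beta0`` are the three baseline-species log odds (levels 2-4 vs 1);
    ``beta1`` the species offsets (None in the reduced model); ``sigma``
    the random-intercept SD.  ``covariance`` covers the free parameters
    in ``param_names`` order.
    """

    beta0: np.ndarray
    beta1: np.ndarray | None
    sigma: float
    sigma_fixed: bool
    covariance: np.ndarray | None
    param_names: list
    loglik: float
    n_individuals: int
    n_choices: int
    n_nodes: int
    converged: bool
    species_levels: list
    warnings: list = field(default_factory=list)

    @property
    def has_species_effect(self) -> bool:
        return self.beta1 is not None

    def linear_predictors(self) -> np.ndarray:
        """(n_species, 4) category utilities at random intercept 0."""
        n_sp = len(self.species_levels)
        eta = np.zeros((n_sp, N_LEVELS))
        eta[:, 1:] += self.beta0
        if self.beta1 is not None and n_sp > 1:
            eta[1, 1:] += self.beta1
        return eta


def _counts_by_bee(df: pd.DataFrame, species_levels) -> tuple[np.ndarray, np.ndarray]:
    """(B, 4) choice counts per bee and (B,) species index."""
    sp_index = {s: i for i, s in enumerate(species_levels)}
    grouped = df.groupby("bee_id", sort=True)
    counts = np.zeros((grouped.ngroups, N_LEVELS))
    species = np.zeros(grouped.ngroups, dtype=int)
    for b, (_, g) in enumerate(grouped):
        sp = g["species"].unique()
        if len(sp) != 1:
            raise ValueError(f"bee {g.name!r} recorded under several species")
        species[b] = sp_index[sp[0]]
        lev, n = np.unique(g["chosen_level"].to_numpy(), return_counts=True)
        counts[b, lev - 1] = n
    return counts, species


def _marginal_loglik(theta, counts, species, n_species, species_effect,
                     sigma_fixed, nodes, weights):
    """Gauss-Hermite marginal log-likelihood.

    The linear predictor depends on a bee only through its species and
    the quadrature node, so the per-(species, node) category log
    probabilities are a small table and the per-bee terms are one matrix
    product with the count matrix.
    """
    k = N_LEVELS - 1
    beta0 = theta[:k]
    pos = k
    if species_effect:
        beta1 = theta[pos:pos + k]
        pos += k
    else:
        beta1 = np.zeros(k)
    sigma = sigma_fixed if sigma_fixed is not None else theta[pos]
    u = np.sqrt(2.0) * sigma * nodes                  # (J,)
    logw = np.log(weights) - 0.5 * np.log(np.pi)      # normalised GH weights

    total = 0.0
    for s in range(n_species):
        mask = species == s
        if not mask.any():
            continue
        eta = np.zeros((nodes.size, N_LEVELS))        # (J, 4)
        eta[:, 1:] = beta0 + s * beta1 + u[:, None]
        logp = eta - logsumexp(eta, axis=1, keepdims=True)
        per_bee_node = counts[mask] @ logp.T          # (B_s, J)
        total += logsumexp(per_bee_node + logw, axis=1).sum()
    return total


def _numerical_hessian(f, x, h_rel=1e-4):
    """Central-difference Hessian of scalar ``f`` at ``x``."""
    n = x.size
    h = h_rel * (1.0 + np.abs(x))
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej)
                    - f(x - ei + ej) + f(x - ei - ej)
                ) / (4.0 * h[i] * h[j])
    return H


def fit_model(dataset: ChoiceDataset, species_effect: bool = True,
              sigma: float | None = None, n_nodes: int = 21,
              compute_cov: bool = True,
              extra_starts=None) -> CategoryLogitFit:
    """Fit the mixed baseline-category logit by maximum marginal likelihood.

    Parameters
    ----------
    species_effect
        Include the three category-by-species terms (the full model);
        the reduced model drops them for the species LRT.
    sigma
        Fix the random-intercept SD at this value (``0`` gives the plain
        multinomial logit); ``None`` estimates it (bounded in [0, 5]).
    n_nodes
        Gauss-Hermite node count for the marginal likelihood.
    compute_cov
        Compute the covariance of the free parameters from the numerical
        Hessian (skippable in Monte-Carlo loops that only need logliks).
    extra_starts
        Additional starting vectors to try (e.g. a warm start from the
        reduced fit); the best optimum is kept.

    Non-convergence is flagged (``converged=False``), never silent; a
    never-chosen level within a species stratum attaches a separation
    warning instead of fabricating finite estimates.
    """
    df = dataset.records
    if len(df) == 0:
        raise ValueError("empty choice dataset")
    species_levels = dataset.species_levels
    n_species = len(species_levels)
    if species_effect and n_species < 2:
        raise ValueError("species effect requires both species in the data")
    if n_species > 2:
        raise ValueError("at most two species supported")
    counts, species = _counts_by_bee(df, species_levels)

    warnings = []
    for s, name in enumerate(species_levels):
        cell = counts[species == s].sum(axis=0)
        zero = np.flatnonzero(cell == 0) + 1
        if zero.size:
            warnings.append(
                f"separation: species {name!r} never chose level(s) "
                f"{zero.tolist()}; the corresponding log odds diverge")

    k = N_LEVELS - 1
    nodes, weights = np.polynomial.hermite.hermgauss(int(n_nodes))
    estimate_sigma = sigma is None
    sigma_fixed = None if estimate_sigma else float(sigma)
    if sigma_fixed == 0.0:
        nodes, weights = np.zeros(1), np.array([np.sqrt(np.pi)])

    def negll(theta):
        return -_marginal_loglik(theta, counts, species, n_species,
                                 species_effect, sigma_fixed, nodes, weights)

    # start at smoothed empirical log count ratios
    overall = counts.sum(axis=0) + 0.5
    start0 = np.log(overall[1:] / overall[0])
    starts = []
    base = [start0]
    if species_effect:
        by_sp = [counts[species == s].sum(axis=0) + 0.5 for s in range(2)]
        lo = [np.log(c[1:] / c[0]) for c in by_sp]
        base = [np.concatenate([lo[0], lo[1] - lo[0]])]
    for b in base:
        starts.append(np.concatenate([b, [0.3]]) if estimate_sigma else b)
    if extra_starts is not None:
        starts.extend(np.asarray(s, dtype=float) for s in extra_starts)

    n_free = k * (2 if species_effect else 1) + (1 if estimate_sigma else 0)
    bounds = [(None, None)] * (n_free - (1 if estimate_sigma else 0))
    if estimate_sigma:
        bounds.append((0.0, 5.0))

    best = None
    for x0 in starts:
        if x0.size != n_free:
            raise ValueError("starting vector has wrong length")
        res = optimize.minimize(negll, x0, method="L-BFGS-B", bounds=bounds,
                                jac="3-point",
                                options={"maxiter": 500, "ftol": 1e-14,
                                         "gtol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    # under separation the likelihood is flat in the diverging direction
    # and the line search can abort at what is still an optimum; accept
    # any point with a negligible (projected) gradient
    grad = np.atleast_1d(best.jac) if best.jac is not None else None
    converged = bool(best.success)
    if not converged and grad is not None:
        proj = grad.copy()
        for j, (lo_b, hi_b) in enumerate(bounds):
            if lo_b is not None and abs(theta[j] - lo_b) < 1e-12 and proj[j] > 0:
                proj[j] = 0.0
            if hi_b is not None and abs(theta[j] - hi_b) < 1e-12 and proj[j] < 0:
                proj[j] = 0.0
        converged = bool(np.max(np.abs(proj)) < 1e-3)
    beta0 = theta[:k]
    beta1 = theta[k:2 * k] if species_effect else None
    sig = float(theta[-1]) if estimate_sigma else sigma_fixed

    names = [f"beta0_{lev}" for lev in range(2, N_LEVELS + 1)]
    if species_effect:
        names += [f"beta1_{lev}" for lev in range(2, N_LEVELS + 1)]
    if estimate_sigma:
        names += ["sigma"]

    cov = None
    if compute_cov:
        H = _numerical_hessian(negll, theta)
        cov = np.linalg.pinv(H)
        cov = 0.5 * (cov + cov.T)

    return CategoryLogitFit(
        beta0=beta0, beta1=beta1, sigma=sig, sigma_fixed=not estimate_sigma,
        covariance=cov, param_names=names, loglik=-float(best.fun),
        n_individuals=counts.shape[0], n_choices=int(counts.sum()),
        n_nodes=int(n_nodes), converged=converged,
        species_levels=list(species_levels), warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Reporting


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class LogOddsRow:
    """One predicted log odds ratio (level k vs baseline) for one species."""

    species: str
    pair: str
    estimate: float
    se: float
    ci95: tuple
    p: float
    stars: str


def log_odds_table(fit: CategoryLogitFit, pair_prefix: str = "L") -> list[LogOddsRow]:
    """Per-species log odds of levels 2-4 vs the baseline, with Wald
    95% CIs (estimate +/- 1.96 SE) and significance stars at the
    0.05/0.01/0.001 two-sided thresholds."""
    if not fit.converged:
        raise ValueError("cannot tabulate a non-converged fit")
    if fit.covariance is None:
        raise ValueError("fit carries no covariance (compute_cov=False)")
    k = N_LEVELS - 1
    rows = []
    for s, sp_name in enumerate(fit.species_levels):
        for j in range(k):
            est = fit.beta0[j]
            var = fit.covariance[j, j]
            if s == 1 and fit.beta1 is not None:
                est = est + fit.beta1[j]
                var = var + fit.covariance[k + j, k + j] \
                    + 2.0 * fit.covariance[j, k + j]
            se = float(np.sqrt(max(var, 0.0)))
            z = est / se if se > 0 else np.inf * np.sign(est)
            p = float(2.0 * stats.norm.sf(abs(z)))
            rows.append(LogOddsRow(
                species=sp_name,
                pair=f"{pair_prefix}{j + 2}/{pair_prefix}1",
                estimate=float(est), se=se,
                ci95=(float(est - 1.96 * se), float(est + 1.96 * se)),
                p=p, stars=_stars(p)))
    return rows


def log_odds_frame(rows) -> pd.DataFrame:
    return pd.DataFrame([{
        "species": r.species, "pair": r.pair, "log_odds": r.estimate,
        "se": r.se, "ci_low": r.ci95[0], "ci_high": r.ci95[1],
        "p": r.p, "stars": r.stars} for r in rows])


@dataclass(frozen=True)
class LRTResult:
    chi2: float
    df: int
    p: float


def lrt_species(fit_full: CategoryLogitFit,
                fit_reduced: CategoryLogitFit) -> LRTResult:
    """Likelihood-ratio test of the species terms (df = 3).

    chi2 = 2 (loglik_full - loglik_reduced); a full loglik below the
    reduced one beyond numerical tolerance indicates a failed fit and
    raises.
    """
    if fit_full.beta1 is None:
        raise ValueError("fit_full must contain the species terms")
    chi2 = 2.0 * (fit_full.loglik - fit_reduced.loglik)
    if chi2 < -1e-4:
        raise RuntimeError(
            f"full-model loglik below reduced ({chi2 / 2:.6f}); fit failure")
    chi2 = max(chi2, 0.0)
    df = len(fit_full.beta1)
    return LRTResult(float(chi2), df, float(stats.chi2.sf(chi2, df)))


def predicted_proportions(fit: CategoryLogitFit) -> pd.DataFrame:
    """Population-level choice probabilities over levels 1-4 per species
    (softmax of the fixed-effect utilities, random intercept at 0)."""
    if not fit.converged:
        raise ValueError("cannot predict from a non-converged fit")
    eta = fit.linear_predictors()
    p = np.exp(eta - logsumexp(eta, axis=1, keepdims=True))
    return pd.DataFrame(p, index=fit.species_levels,
                        columns=[f"level_{j}" for j in range(1, N_LEVELS + 1)])
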