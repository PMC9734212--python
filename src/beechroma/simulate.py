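"""Synthetic inputs: pigment-mixture spectra, controlled 4-level stimulus
series, simulated bee choice datasets and arena placements.

The generator mirrors the experimental design: blue pigment blends
desaturated or darkened by white/black admixture to give 4-level series
constant in hue and in one of {spectral purity, intensity}; choice
datasets of 20 bees x 5 choices per condition with per-bee
heterogeneity; and a 6 x 6 stimulus grid inside a 50 cm circular arena
with 3 cm minimum spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import hexagon
from .choice import CHOICE_COLUMNS, N_LEVELS, ChoiceDataset
from .spectra import DEFAULT_GRID, SpectralCurve

__all__ = [
    "PigmentMix",
    "PigmentBases",
    "InfeasibleDesignError",
    "SimulationDesign",
    "ArenaLayout",
    "default_bases",
    "mix_pigment_spectra",
    "design_stimulus_series",
    "StimulusSeries",
    "simulate_choices",
    "arena_positions",
]


class InfeasibleDesignError(ValueError):
    """A requested stimulus series falls outside the pigment gamut."""


@dataclass(frozen=True)
class PigmentBases:
    """Base reflectances of the blue blend and the achromatic powders."""

    blue: SpectralCurve
    white: SpectralCurve
    black: SpectralCurve

    def curves(self):
        return (self.blue, self.white, self.black)


@dataclass(frozen=True)
class PigmentMix:
    """Convex mixing weights over (blue blend, white, black)."""

    w_blue: float
    w_white: float
    w_black: float
    bases: PigmentBases

    def __post_init__(self):
        w = np.array([self.w_blue, self.w_white, self.w_black])
        if np.any(w < 0):
            raise ValueError("pigment weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"pigment weights must sum to 1 (got {w.sum()!r})")


def blue_pigments(grid=None) -> tuple[SpectralCurve, SpectralCurve]:
    """Two synthetic blue artist pigments whose blend sets the hue.

    Broadband Gaussian reflectances over a dark pedestal, peaking at
    430 nm ("sky blue") and 470 nm ("ultramarine"); blending them moves
    the dominant wavelength of the mixture, which is how the hue of the
    stimulus series is steered.  Modelling stand-ins, not measured
    pigment spectra.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    short = 0.05 + 0.50 * np.exp(-0.5 * ((grid - 430.0) / 28.0) ** 2)
    long_ = 0.05 + 0.50 * np.exp(-0.5 * ((grid - 470.0) / 32.0) ** 2)
    return (SpectralCurve(grid, short, "reflectance", "blue_short"),
            SpectralCurve(grid, long_, "reflectance", "blue_long"))


def blend_blue(balance: float, grid=None) -> SpectralCurve:
    """Blue blend: ``balance`` parts short-wavelength pigment to
    ``1 - balance`` parts long-wavelength pigment."""
    if not (0.0 <= balance <= 1.0):
        raise ValueError("balance must be in [0, 1]")
    a, b = blue_pigments(grid)
    vals = balance * a.values + (1.0 - balance) * b.values
    return SpectralCurve(a.wavelengths, vals, "reflectance",
                         f"blue_blend_{balance:.2f}")


def default_bases(grid=None, blue_balance: float = 0.5) -> PigmentBases:
    """Base reflectances emulating the study's pigments: an equal-parts
    blue blend plus spectrally flat white (0.90) and black (0.05)."""
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    return PigmentBases(
        blue=blend_blue(blue_balance, grid),
        white=SpectralCurve(grid, np.full(grid.shape, 0.90), "reflectance", "white"),
        black=SpectralCurve(grid, np.full(grid.shape, 0.05), "reflectance", "black"),
    )


def mix_pigment_spectra(mix: PigmentMix, mode: str = "linear",
                        name: str = "") -> SpectralCurve:
    """Reflectance of a pigment mixture.

    ``linear`` mode takes the convex combination of the base
    reflectances.  ``subtractive`` mode mixes Kubelka-Munk
    absorption/scatter ratios K/S = (1-R)^2 / (2R) linearly by weight
    and inverts back to reflectance, a standard single-constant model of
    opaque powder mixing.
    """
    bases = mix.bases
    grid = bases.blue.wavelengths
    w = np.array([mix.w_blue, mix.w_white, mix.w_black])
    R = np.vstack([c.values for c in bases.curves()])
    if mode == "linear":
        vals = w @ R
    elif mode == "subtractive":
        Rc = np.clip(R, 1e-6, 1.0 - 1e-9)
        ks = (1.0 - Rc) ** 2 / (2.0 * Rc)
        ks_mix = w @ ks
        vals = 1.0 + ks_mix - np.sqrt(ks_mix ** 2 + 2.0 * ks_mix)
    else:
        raise ValueError(f"unknown mixing mode {mode!r}")
    return SpectralCurve(grid, vals, "reflectance", name)


# ---------------------------------------------------------------------------
# Stimulus-series design


@dataclass(frozen=True)
class StimulusSeries:
    """A designed 4-level series with its metrics and validation report.

    ``weights`` holds one (blue_short, blue_long, white, black) weight
    tuple per level.
    """

    varying: str
    curves: list
    metrics: list
    report: "hexagon.SeriesReport"
    weights: list


class _MixtureGamut:
    """Helper over the (hue c, blue weight a, white share b) mixture space.

    c blends the two blue pigments (share of the short-wavelength one),
    a is the blue-blend weight against the achromatic remainder, and b
    is the white share of that remainder.  Intensity evaluations skip
    the locus geometry, which keeps the nested root-finding cheap.
    """

    def __init__(self, context, locus_table, mode, bases=None):
        self.context = context
        self.locus_table = locus_table
        self.mode = mode
        grid = context.grid
        if bases is None:
            self.blue_short, self.blue_long = blue_pigments(grid)
            self.white, self.black = default_bases(grid).white, default_bases(grid).black
            self.steerable = True
        else:
            self.blue_short = self.blue_long = bases.blue
            self.white, self.black = bases.white, bases.black
            self.steerable = False

    def curve(self, c, a, b, name=""):
        blue = (c * self.blue_short.values + (1.0 - c) * self.blue_long.values)
        grid = self.context.grid
        R = np.vstack([blue, self.white.values, self.black.values])
        w = np.array([a, (1.0 - a) * b, (1.0 - a) * (1.0 - b)])
        if self.mode == "linear":
            vals = w @ R
        else:
            Rc = np.clip(R, 1e-6, 1.0 - 1e-9)
            ks = w @ ((1.0 - Rc) ** 2 / (2.0 * Rc))
            vals = 1.0 + ks - np.sqrt(ks ** 2 + 2.0 * ks)
        return SpectralCurve(grid, vals, "reflectance", name)

    def intensity(self, c, a, b):
        E = hexagon.excitations(self.curve(c, a, b), self.context)
        return hexagon.intensity(E)

    def metrics(self, c, a, b, name=""):
        return hexagon.compute_metrics(self.curve(c, a, b, name), self.context,
                                       self.locus_table)

    def solve_b(self, c, a, target_I):
        """White share giving intensity ``target_I`` (I increases in b)."""
        def f(b):
            return self.intensity(c, a, b) - target_I
        lo, hi = f(0.0), f(1.0)
        if not (lo <= 0.0 <= hi):
            raise InfeasibleDesignError(
                f"intensity {target_I:.3f} outside the gamut "
                f"[{lo + target_I:.3f}, {hi + target_I:.3f}] at blue weight {a:.3f}")
        return brentq(f, 0.0, 1.0, xtol=1e-10)

    def a_max_for_intensity(self, c, target_I):
        """Largest blue weight at which ``target_I`` is still reachable.

        Feasibility requires I(c, a, 0) <= target <= I(c, a, 1); the
        dark (b = 0) branch binds for targets below the blue blend's own
        intensity, the light (b = 1) branch for targets above it.
        """
        blend_I = self.intensity(c, 1.0, 0.0)     # b irrelevant at a = 1
        lo = self.intensity(c, 0.0, 0.0)          # pure black
        hi = self.intensity(c, 0.0, 1.0)          # pure white
        if not (lo <= target_I <= hi):
            raise InfeasibleDesignError(
                f"intensity {target_I:.3f} outside the pigment gamut "
                f"[{lo:.3f}, {hi:.3f}]")
        if abs(target_I - blend_I) < 1e-12:
            return 1.0
        if target_I > blend_I:
            f = lambda a_: self.intensity(c, a_, 1.0) - target_I
        else:
            f = lambda a_: self.intensity(c, a_, 0.0) - target_I
        a = brentq(f, 0.0, 1.0, xtol=1e-9)
        return a * (1.0 - 1e-9)

    def sp_at(self, c, a, target_I):
        """Purity of the held-intensity mixture at (c, a)."""
        b = self.solve_b(c, a, target_I)
        m = self.metrics(c, a, b)
        if m.flag == "non_spectral":
            raise InfeasibleDesignError("mixture fell in the bee-purple sector")
        return m.spectral_purity

    def solve_a_for_sp(self, c, target_sp, target_I):
        """Blue weight giving purity ``target_sp`` at held intensity
        (purity increases in a at fixed intensity)."""
        a_hi = self.a_max_for_intensity(c, target_I)
        sp_hi = self.sp_at(c, a_hi, target_I)
        if not (0.0 <= target_sp <= sp_hi):
            raise InfeasibleDesignError(
                f"spectral purity {target_sp:.3f} outside the feasible "
                f"[0, {sp_hi:.3f}] at intensity {target_I:.3f}")
        return brentq(lambda a_: self.sp_at(c, a_, target_I) - target_sp,
                      0.0, a_hi, xtol=1e-9)

    def solve_level(self, c, target_sp, target_I):
        """(a, b) hitting both purity and intensity targets at hue knob c."""
        a = self.solve_a_for_sp(c, target_sp, target_I)
        b = self.solve_b(c, a, target_I)
        return a, b

    def steer_hue(self, lambda_star, target_sp, target_I, c_lo=0.02, c_hi=0.98):
        """Hue knob c whose solved level has dominant wavelength
        ``lambda_star`` (lambda_d decreases in the short-blue share)."""
        def lam(c):
            a, b = self.solve_level(c, target_sp, target_I)
            return self.metrics(c, a, b).lambda_d
        f_lo, f_hi = lam(c_lo) - lambda_star, lam(c_hi) - lambda_star
        if f_lo * f_hi > 0:
            raise InfeasibleDesignError(
                f"hue {lambda_star:.1f} nm not reachable at SP={target_sp:.3f}, "
                f"I={target_I:.3f}: attainable "
                f"[{min(f_lo, f_hi) + lambda_star:.1f}, "
                f"{max(f_lo, f_hi) + lambda_star:.1f}] nm")
        c = brentq(lambda c_: lam(c_) - lambda_star, c_lo, c_hi, xtol=1e-4)
        return (c, *self.solve_level(c, target_sp, target_I))


def _level_targets(lo, hi, rng, jitter):
    """Four strictly increasing level targets inside [lo, hi]; evenly
    spaced with a margin, jittered when requested."""
    margin = 0.08 * (hi - lo)
    base = np.linspace(lo + margin, hi - margin, 4)
    if jitter:
        gap = (base[1] - base[0]) * 0.25
        base = np.sort(base + rng.uniform(-gap, gap, size=4))
    return base


def design_stimulus_series(vary: str, context, bases: PigmentBases | None = None,
                           n_levels: int = 4, mode: str = "linear",
                           hold_intensity: float = 0.45,
                           hold_purity: float = 0.25,
                           tol_hue: float = 5.0, tol_hold: float = 0.02,
                           seed: int | None = None) -> StimulusSeries:
    """Design a 4-level pigment-mixture series varying one colour parameter.

    For ``vary="purity"`` the four stimuli increase strictly in spectral
    purity at constant intensity (``hold_intensity``); for
    ``vary="intensity"`` they increase in intensity at constant spectral
    purity (``hold_purity``).  The held parameter is met by 1-D root
    refinement of the mixing weights after a coarse feasibility scan,
    and the hue is held constant by steering the balance of the two blue
    pigments so every level shares the dominant wavelength of the
    mid-series reference (diluting a single blend with white/black
    rotates its chromatic direction, so hue must be actively steered;
    with user-supplied 3-pigment ``bases`` there is no hue knob and the
    drift is only checked).  With a ``seed`` the level targets are
    jittered within the feasible band, otherwise they are evenly
    spaced; the search is deterministic given the seed.  The result is
    validated with :func:`hexagon.validate_series`;
    :class:`InfeasibleDesignError` names the binding constraint when the
    request leaves the pigment gamut.
    """
    if n_levels != 4:
        raise ValueError("the experimental design uses exactly 4 levels")
    if vary not in ("purity", "intensity"):
        raise ValueError("vary must be 'purity' or 'intensity'")
    locus_table = hexagon.spectral_locus(context)
    gamut = _MixtureGamut(context, locus_table, mode, bases)
    rng = np.random.default_rng(seed)
    c0 = 0.5

    if vary == "purity":
        # purity ceiling over the whole hue-steering range, so every
        # level stays solvable at any blend the hue search visits
        sp_hi = 0.97 * min(
            gamut.sp_at(c, gamut.a_max_for_intensity(c, hold_intensity),
                        hold_intensity)
            for c in np.linspace(0.02, 0.98, 9))
        if sp_hi < 0.1:
            raise InfeasibleDesignError(
                f"holding intensity at {hold_intensity} leaves almost no "
                f"purity range (max {sp_hi:.3f}); widen the pigment gamut")
        sp_targets = _level_targets(0.0, sp_hi, rng, seed is not None)
        pairs = [(t, hold_intensity) for t in sp_targets]   # (SP, I) per level
        names = [f"SP{k}" for k in range(1, 5)]
    else:
        i_grid = np.linspace(0.22, 0.80, 30)
        feasible = []
        for tI in i_grid:
            try:
                for c in np.linspace(0.02, 0.98, 9):
                    gamut.solve_a_for_sp(c, hold_purity, tI)
            except InfeasibleDesignError:
                continue
            feasible.append(tI)
        if len(feasible) < 4:
            raise InfeasibleDesignError(
                f"holding spectral purity at {hold_purity} leaves fewer than "
                "4 feasible intensities; widen the pigment gamut")
        i_targets = _level_targets(min(feasible), max(feasible), rng,
                                   seed is not None)
        pairs = [(hold_purity, t) for t in i_targets]
        names = [f"I{k}" for k in range(1, 5)]

    # hue reference: mid-series level at the neutral blend
    mid_sp = 0.5 * (pairs[1][0] + pairs[2][0])
    mid_i = 0.5 * (pairs[1][1] + pairs[2][1])
    a_m, b_m = gamut.solve_level(c0, mid_sp, mid_i)
    lambda_star = gamut.metrics(c0, a_m, b_m).lambda_d

    curves, metrics, weights = [], [], []
    for (t_sp, t_i), name in zip(pairs, names):
        if gamut.steerable:
            c, a, b = gamut.steer_hue(lambda_star, t_sp, t_i)
        else:
            c, (a, b) = c0, gamut.solve_level(c0, t_sp, t_i)
        m = gamut.metrics(c, a, b, name=name)
        curves.append(gamut.curve(c, a, b, name=name))
        metrics.append(m)
        ach = 1.0 - a
        weights.append((a * c, a * (1.0 - c), ach * b, ach * (1.0 - b)))
    report = hexagon.validate_series(metrics, vary, tol_hue=tol_hue,
                                     tol_hold=tol_hold)
    if not report.passed:
        raise InfeasibleDesignError(
            f"designed {vary} series failed validation: {report}")
    return StimulusSeries(vary, curves, metrics, report, weights)


# ---------------------------------------------------------------------------
# Choice simulation


@dataclass(frozen=True)
class SimulationDesign:
    """Design of one simulated test condition.

    ``species_probs`` maps each species to its population-level choice
    probabilities over the four stimulus levels; ``sigma_individual`` is
    the SD of the per-bee random intercept shared across the non-baseline
    category logits, matching the fitted model's structure.
    """

    species_probs: dict
    n_bees_per_group: int = 20
    choices_per_bee: int = 5
    sigma_individual: float = 0.0
    seed: int | None = None
    parameter: str = "purity"
    trained_level: str = "high"

    def __post_init__(self):
        for sp, p in self.species_probs.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (N_LEVELS,) or np.any(p < 0) or abs(p.sum() - 1) > 1e-9:
                raise ValueError(f"probabilities for {sp!r} must be a 4-vector summing to 1")
        if self.n_bees_per_group < 1 or self.choices_per_bee < 1:
            raise ValueError("need at least one bee and one choice")
        if self.sigma_individual < 0:
            raise ValueError("sigma_individual must be >= 0")


def simulate_choices(design: SimulationDesign) -> ChoiceDataset:
    """Simulate a choice dataset under the baseline-category logit model.

    Per bee a shared intercept shift u ~ Normal(0, sigma^2) is added to
    the log odds of levels 2-4 versus level 1; each of the bee's choices
    is an independent draw from the resulting softmax.  Reproducible
    under ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    for sp in sorted(design.species_probs):
        logp = np.log(np.clip(np.asarray(design.species_probs[sp], dtype=float),
                              1e-300, None))
        for i in range(design.n_bees_per_group):
            u = rng.normal(0.0, design.sigma_individual)
            eta = logp.copy()
            eta[1:] += u
            p = np.exp(eta - eta.max())
            p /= p.sum()
            levels = rng.choice(N_LEVELS, size=design.choices_per_bee, p=p) + 1
            for rank, lev in enumerate(levels, start=1):
                rows.append({
                    "bee_id": f"{sp}_{i + 1:03d}",
                    "species": sp,
                    "parameter": design.parameter,
                    "trained_level": design.trained_level,
                    "training_round": 1,
                    "choice_rank": rank,
                    "chosen_level": int(lev),
                })
    df = pd.DataFrame(rows, columns=CHOICE_COLUMNS)
    prov = (f"simulated seed={design.seed} sigma={design.sigma_individual} "
            f"n={design.n_bees_per_group}x{design.choices_per_bee}")
    return ChoiceDataset(df, provenance=prov)


# ---------------------------------------------------------------------------
# Arena geometry


@dataclass(frozen=True)
class ArenaLayout:
    """6 x 6 position grid over the inscribed square of a circular arena."""

    rows: int = 6
    cols: int = 6
    arena_diameter_cm: float = 50.0
    min_spacing_cm: float = 3.0

    def centres(self) -> np.ndarray:
        """(rows*cols, 2) cell-centre coordinates in cm, row-major from
        top-left, origin at the arena centre."""
        side = self.arena_diameter_cm / np.sqrt(2.0)
        xs = (np.arange(self.cols) + 0.5) / self.cols * side - side / 2.0
        ys = side / 2.0 - (np.arange(self.rows) + 0.5) / self.rows * side
        xx, yy = np.meshgrid(xs, ys)
        return np.column_stack([xx.ravel(), yy.ravel()])


def arena_positions(n_stimuli: int, layout: ArenaLayout | None = None,
                    seed: int | None = None,
                    max_retries: int = 1000) -> pd.DataFrame:
    """Sample distinct stimulus positions on the arena grid.

    Uniform sampling without replacement, rejecting draws with any pair
    closer than the layout's minimum spacing (re-randomisation of
    clashing placements).  Returns a frame with row, col and centre
    coordinates in cm.
    """
    layout = layout or ArenaLayout()
    n_cells = layout.rows * layout.cols
    if n_stimuli > n_cells:
        raise ValueError(f"{n_stimuli} stimuli exceed the {n_cells} grid positions")
    centres = layout.centres()
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        idx = rng.choice(n_cells, size=n_stimuli, replace=False)
        pts = centres[idx]
        diff = pts[:, None, :] - pts[None, :, :]
        dist = np.sqrt((diff ** 2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        if dist.min() >= layout.min_spacing_cm:
            rows, cols = idx // layout.cols, idx % layout.cols
            return pd.DataFrame({"row": rows, "col": cols,
                                 "x_cm": pts[:, 0], "y_cm": pts[:, 1]})
    raise RuntimeError(
        f"could not satisfy {layout.min_spacing_cm} cm spacing for "
        f"{n_stimuli} stimuli after {max_retries} draws")
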