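"""Colour-hexagon model of hymenopteran trichromatic vision.

Receptor quantum catches under von Kries adaptation to the background,
the saturating excitation transform E = P/(P+1), Chittka's hexagon
coordinates, the monochromatic spectral locus, dominant wavelength by
ray-polyline intersection, and the derived stimulus metrics: colour
contrast, spectral purity SP, intensity I = (E_UV+E_B+E_G)/3 and green
contrast GC = E_G - 0.5.

Under von Kries adaptation the adapted background sits exactly at the
hexagon centre, so "distance from the background locus" and "distance
from the centre" coincide and both are implemented as distance from the
origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import trapezoid
from scipy.optimize import minimize_scalar

from .spectra import SpectralCurve, ReceptorSet, resample

__all__ = [
    "NonSpectralError",
    "ReceptorExcitations",
    "HexLocus",
    "SpectralLocusTable",
    "ViewingContext",
    "ColourMetrics",
    "SeriesReport",
    "make_context",
    "excitations",
    "excitation_from_catch",
    "hex_coords",
    "hex_distance",
    "spectral_locus",
    "dominant_wavelength",
    "DominantWavelength",
    "spectral_purity",
    "intensity",
    "green_contrast",
    "compute_metrics",
    "metrics_table",
    "metrics_frame",
    "validate_series",
]

#: Hexagon distance below which a locus is treated as achromatic.
ACHROMATIC_TOL = 1e-3


class NonSpectralError(ValueError):
    """The stimulus lies in the bee-purple sector: its chromatic direction
    does not meet the spectral locus, so no dominant wavelength exists."""


def excitation_from_catch(P):
    """Saturating receptor transform E = P/(P+1), bounded in [0, 1)."""
    P = np.asarray(P, dtype=float)
    return P / (P + 1.0)


@dataclass(frozen=True)
class ReceptorExcitations:
    """Quantum catches P and excitations E for the UV, blue, green receptors."""

    P: np.ndarray
    E: np.ndarray

    @classmethod
    def from_catches(cls, P) -> "ReceptorExcitations":
        P = np.asarray(P, dtype=float)
        if np.any(P < 0):
            raise ValueError("quantum catches must be nonnegative")
        return cls(P, excitation_from_catch(P))


@dataclass(frozen=True)
class HexLocus:
    """A point in the colour hexagon (dimensionless coordinates)."""

    x: float
    y: float

    @property
    def distance(self) -> float:
        """Hexagon distance from the centre (= adapted background locus)."""
        return float(np.hypot(self.x, self.y))

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y])


def hex_coords(E) -> HexLocus:
    """Hexagon coordinates from the three excitations (E_UV, E_B, E_G):

    x = (sqrt(3)/2) (E_G - E_UV),  y = E_B - (E_UV + E_G)/2.
    """
    if isinstance(E, ReceptorExcitations):
        E = E.E
    e_uv, e_b, e_g = (float(v) for v in E)
    x = (np.sqrt(3.0) / 2.0) * (e_g - e_uv)
    y = e_b - (e_uv + e_g) / 2.0
    return HexLocus(x, y)


def hex_distance(a: HexLocus, b: HexLocus) -> float:
    """Euclidean (perceptual) distance between two hexagon loci."""
    return float(np.hypot(a.x - b.x, a.y - b.y))


@dataclass(frozen=True)
class SpectralLocusTable:
    """Hexagon loci of monochromatic lights over a wavelength range."""

    wavelength: np.ndarray          # nm, increasing
    xy: np.ndarray                  # (n, 2) hexagon coordinates
    flux_used: np.ndarray           # photon flux applied per wavelength
    mode: str                       # "max_distance" | "fixed_flux"

    def locus_at(self, lam: float) -> HexLocus:
        """Locus at ``lam``, linearly interpolated between table rows."""
        x = np.interp(lam, self.wavelength, self.xy[:, 0])
        y = np.interp(lam, self.wavelength, self.xy[:, 1])
        return HexLocus(float(x), float(y))


@dataclass
class ViewingContext:
    """Illuminant, background and receptors with cached von Kries gains.

    The gains R_i normalise the quantum catch of the adapting background
    to 1, so that the background's excitation is exactly 0.5 in every
    channel and its locus is the hexagon centre.
    """

    grid: np.ndarray
    illuminant: SpectralCurve
    background: SpectralCurve
    receptors: ReceptorSet
    von_kries_R: np.ndarray
    _locus_cache: dict = field(default_factory=dict, repr=False)

    def sensitivity_matrix(self) -> np.ndarray:
        """(3, n) array of receptor sensitivities on the context grid."""
        return np.vstack([c.values for c in self.receptors.curves()])


def make_context(illuminant: SpectralCurve, background: SpectralCurve,
                 receptors: ReceptorSet, grid=None) -> ViewingContext:
    """Build a viewing context; all curves are resampled to one grid.

    Raises ``ValueError`` when a receptor has zero overlap with the
    background under the illuminant (adaptation undefined).
    """
    grid = illuminant.wavelengths if grid is None else np.asarray(grid, dtype=float)
    ill = resample(illuminant, grid)
    bkg = resample(background, grid)
    rec = ReceptorSet(
        *(resample(c, grid) for c in receptors.curves()),
        lambda_max=receptors.lambda_max,
        species_label=receptors.species_label,
    )
    S = np.vstack([c.values for c in rec.curves()])
    integrals = trapezoid(bkg.values * ill.values * S, grid, axis=1)
    if np.any(integrals <= 0) or not np.all(np.isfinite(integrals)):
        bad = ["uv", "blue", "green"][int(np.argmin(integrals))]
        raise ValueError(
            f"background x illuminant x sensitivity integral is not positive "
            f"for the {bad} receptor; von Kries adaptation is undefined"
        )
    R = 1.0 / integrals
    return ViewingContext(grid, ill, bkg, rec, R)


def excitations(stimulus: SpectralCurve, context: ViewingContext) -> ReceptorExcitations:
    """Receptor quantum catches and excitations of a reflecting stimulus.

    P_i = R_i * integral(stimulus x illuminant x S_i) by the trapezoid
    rule on the context grid; E_i = P_i/(P_i+1).
    """
    if stimulus.kind != "reflectance":
        raise ValueError("stimulus must be a reflectance curve")
    stim = stimulus if np.array_equal(stimulus.wavelengths, context.grid) \
        else resample(stimulus, context.grid)
    S = context.sensitivity_matrix()
    P = context.von_kries_R * trapezoid(
        stim.values * context.illuminant.values * S, context.grid, axis=1)
    return ReceptorExcitations.from_catches(P)


def intensity(E) -> float:
    """Intensity I: the mean of the three receptor excitations."""
    if isinstance(E, ReceptorExcitations):
        E = E.E
    return float(np.mean(np.asarray(E, dtype=float)))


def green_contrast(E) -> float:
    """Green contrast GC = E_G - 0.5 (the achromatic detection channel)."""
    if isinstance(E, ReceptorExcitations):
        E = E.E
    return float(np.asarray(E, dtype=float)[2] - 0.5)


# ---------------------------------------------------------------------------
# Spectral locus and dominant wavelength


def _mono_locus(context: ViewingContext, lam: float, flux: float) -> HexLocus:
    """Hexagon locus of a monochromatic light of photon flux ``flux`` at
    ``lam`` nm viewed in ``context`` (catches need no integral: the line
    spectrum samples each sensitivity at one wavelength)."""
    S = np.array([float(c(np.array([lam]))[0]) for c in context.receptors.curves()])
    P = context.von_kries_R * flux * S
    return hex_coords(excitation_from_catch(P))


def spectral_locus(context: ViewingContext, lam_range=(300.0, 650.0),
                   mode: str = "max_distance", flux: float | None = None,
                   step: float = 1.0) -> SpectralLocusTable:
    """Table of monochromatic-light loci over ``lam_range``.

    In ``max_distance`` mode (default) the photon flux at each wavelength
    is chosen by a bounded 1-D search to maximise the locus distance
    from the centre.  The search is bounded so that the most sensitive
    receptor's quantum catch stays within [1e-3, 10] of the adapting
    background's (catch 1): expressing the bound in catch rather than
    absolute flux makes the locus invariant to the illuminant scale,
    and the upper bound excludes the degenerate ultra-bright regime in
    which the pigment templates' long tails let two receptors saturate
    and the locus of every mid-spectrum wavelength collapses toward a
    hexagon corner.  In ``fixed_flux`` mode the caller's
    ``flux`` is applied at every wavelength.  The table is cached on the
    context per (range, mode, flux, step).
    """
    key = (tuple(lam_range), mode, flux, step)
    cached = context._locus_cache.get(key)
    if cached is not None:
        return cached
    lo, hi = lam_range
    if lo < context.grid[0] or hi > context.grid[-1]:
        raise ValueError("lam_range outside the context grid")
    lams = np.arange(lo, hi + step / 2, step)
    xy = np.empty((lams.size, 2))
    fluxes = np.empty(lams.size)
    for i, lam in enumerate(lams):
        if mode == "fixed_flux":
            if flux is None:
                raise ValueError("fixed_flux mode requires a flux")
            q = float(flux)
        elif mode == "max_distance":
            S = np.array([float(c(np.array([lam]))[0])
                          for c in context.receptors.curves()])
            catches = context.von_kries_R * S
            peak = np.max(catches)
            if peak <= 0:
                raise RuntimeError(f"flux optimisation failed at {lam:g} nm: "
                                   "all receptors blind")
            # optimise in normalised-catch space: the objective and the
            # [-3, 1] log bracket are then independent of the illuminant
            # scale, so the locus is exactly scale-invariant
            snorm = catches / peak

            def neg_distance(lq):
                E = excitation_from_catch(snorm * 10.0 ** lq)
                return -hex_coords(E).distance

            res = minimize_scalar(neg_distance, bounds=(-3.0, 1.0),
                                  method="bounded", options={"xatol": 1e-6})
            if not res.success:
                raise RuntimeError(f"flux optimisation failed at {lam:g} nm")
            # locus from the scale-free catches themselves, so tables for
            # rescaled illuminants agree bitwise
            loc = hex_coords(excitation_from_catch(snorm * 10.0 ** res.x))
            xy[i] = (loc.x, loc.y)
            fluxes[i] = 10.0 ** res.x / peak
            continue
        else:
            raise ValueError(f"unknown locus mode {mode!r}")
        loc = _mono_locus(context, lam, q)
        xy[i] = (loc.x, loc.y)
        fluxes[i] = q
    table = SpectralLocusTable(lams, xy, fluxes, mode)
    context._locus_cache[key] = table
    return table


@dataclass(frozen=True)
class DominantWavelength:
    """Result of the dominant-wavelength construction.

    ``flag`` is ``"spectral"`` (lambda_d and the locus distance along the
    ray are set), ``"achromatic"`` (stimulus at the centre) or
    ``"non_spectral"`` (bee-purple sector: the chromatic direction exits
    between the spectral-locus endpoints).
    """

    lambda_d: float | None
    flag: str
    locus_distance: float | None = None


def dominant_wavelength(locus_table: SpectralLocusTable, stimulus_locus: HexLocus,
                        tol_achromatic: float = ACHROMATIC_TOL) -> DominantWavelength:
    """Dominant wavelength of a stimulus locus.

    Intersects the ray from the centre through the stimulus with the
    spectral-locus polyline; lambda_d is interpolated linearly between
    the bracketing table wavelengths.  When several segments intersect
    (the locus can curl near its UV end) the outermost intersection is
    used.  Returns flags rather than raising.
    """
    d = stimulus_locus.distance
    if d < tol_achromatic:
        return DominantWavelength(None, "achromatic")
    u = stimulus_locus.as_array() / d
    pts = locus_table.xy
    lams = locus_table.wavelength
    p1 = pts[:-1]
    seg = pts[1:] - p1
    # solve t*u - s*seg = p1 per segment
    det = -u[0] * seg[:, 1] + u[1] * seg[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (-p1[:, 0] * seg[:, 1] + p1[:, 1] * seg[:, 0]) / det
        s = (u[0] * p1[:, 1] - u[1] * p1[:, 0]) / det
    hit = (np.abs(det) > 1e-15) & (t > 0) & (s >= -1e-12) & (s <= 1 + 1e-12)
    if not hit.any():
        return DominantWavelength(None, "non_spectral")
    idx = np.flatnonzero(hit)
    i = idx[np.argmax(t[idx])]            # outermost intersection
    frac = min(max(float(s[i]), 0.0), 1.0)
    lam = lams[i] + frac * (lams[i + 1] - lams[i])
    return DominantWavelength(float(lam), "spectral", locus_distance=float(t[i]))


def _endpoint_line_distance(locus_table: SpectralLocusTable,
                            stimulus_locus: HexLocus) -> float:
    """Distance from the centre, along the stimulus ray, to the straight
    line joining the spectral-locus endpoints (the purple line)."""
    d = stimulus_locus.distance
    u = stimulus_locus.as_array() / d
    p1, p2 = locus_table.xy[0], locus_table.xy[-1]
    seg = p2 - p1
    det = -u[0] * seg[1] + u[1] * seg[0]
    if abs(det) < 1e-15:
        raise NonSpectralError("stimulus ray parallel to the purple line")
    t = (-p1[0] * seg[1] + p1[1] * seg[0]) / det
    if t <= 0:
        raise NonSpectralError("stimulus ray does not meet the purple line")
    return float(t)


def spectral_purity(stimulus_locus: HexLocus, locus_table: SpectralLocusTable,
                    tol_achromatic: float = ACHROMATIC_TOL,
                    nonspectral_purple_line: bool = False) -> float:
    """Spectral purity SP of a stimulus locus.

    SP = (hexagon distance of the stimulus from the background locus) /
    (distance of the spectral locus at the stimulus's dominant wavelength
    from the background locus); 0 = achromatic, 1 = monochromatic-
    equivalent.  Bee-purple stimuli raise :class:`NonSpectralError`
    unless ``nonspectral_purple_line`` opts into the endpoint-line
    (purple-line) denominator.
    """
    dw = dominant_wavelength(locus_table, stimulus_locus, tol_achromatic)
    if dw.flag == "achromatic":
        return 0.0
    if dw.flag == "non_spectral":
        if not nonspectral_purple_line:
            raise NonSpectralError(
                "stimulus lies in the bee-purple sector; pass "
                "nonspectral_purple_line=True to use the endpoint-line denominator"
            )
        denom = _endpoint_line_distance(locus_table, stimulus_locus)
    else:
        denom = dw.locus_distance
    return stimulus_locus.distance / denom


# ---------------------------------------------------------------------------
# Batch metrics


@dataclass(frozen=True)
class ColourMetrics:
    """Per-stimulus colour metrics in a fixed viewing context."""

    name: str
    excitations: ReceptorExcitations
    locus: HexLocus
    colour_contrast: float
    lambda_d: float | None
    flag: str                      # spectral | achromatic | non_spectral
    spectral_purity: float | None
    intensity: float
    green_contrast: float


def compute_metrics(stimulus: SpectralCurve, context: ViewingContext,
                    locus_table: SpectralLocusTable | None = None,
                    tol_achromatic: float = ACHROMATIC_TOL) -> ColourMetrics:
    """All colour metrics of one reflectance stimulus.

    A bee-purple stimulus gets flag ``non_spectral`` and SP ``None``
    rather than an exception, so batch runs never abort on one stimulus.
    """
    if locus_table is None:
        locus_table = spectral_locus(context)
    E = excitations(stimulus, context)
    loc = hex_coords(E)
    dw = dominant_wavelength(locus_table, loc, tol_achromatic)
    if dw.flag == "spectral":
        sp = loc.distance / dw.locus_distance
    elif dw.flag == "achromatic":
        sp = 0.0
    else:
        sp = None
    return ColourMetrics(
        name=stimulus.name,
        excitations=E,
        locus=loc,
        colour_contrast=loc.distance,
        lambda_d=dw.lambda_d,
        flag=dw.flag,
        spectral_purity=sp,
        intensity=intensity(E),
        green_contrast=green_contrast(E),
    )


def metrics_table(stimuli, context: ViewingContext,
                  locus_table: SpectralLocusTable | None = None,
                  tol_achromatic: float = ACHROMATIC_TOL) -> list[ColourMetrics]:
    """Metrics for a batch of stimuli, in input order."""
    if locus_table is None:
        locus_table = spectral_locus(context)
    return [compute_metrics(s, context, locus_table, tol_achromatic) for s in stimuli]


def metrics_frame(metrics) -> "pd.DataFrame":
    """Flatten a list of :class:`ColourMetrics` into a DataFrame."""
    import pandas as pd

    rows = []
    for m in metrics:
        e = m.excitations.E
        rows.append({
            "stimulus": m.name,
            "E_UV": e[0], "E_B": e[1], "E_G": e[2],
            "x": m.locus.x, "y": m.locus.y,
            "contrast": m.colour_contrast,
            "lambda_d": np.nan if m.lambda_d is None else m.lambda_d,
            "flag": m.flag,
            "SP": np.nan if m.spectral_purity is None else m.spectral_purity,
            "I": m.intensity,
            "GC": m.green_contrast,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SeriesReport:
    """Pass/fail report for a 4-level stimulus series."""

    varying: str
    hue_ok: bool
    monotone_ok: bool
    hold_ok: bool
    lambda_d_spread: float
    varied_values: tuple
    held_spread: float

    @property
    def passed(self) -> bool:
        return self.hue_ok and self.monotone_ok and self.hold_ok


def validate_series(metrics, varying: str, tol_hue: float = 5.0,
                    tol_hold: float = 0.02) -> SeriesReport:
    """Check that a 4-level series varies one colour parameter only.

    Criteria: (a) dominant wavelengths agree within ``tol_hue`` nm;
    (b) the varied parameter (SP or I) is strictly increasing over
    levels 1-4; (c) the held parameter stays within ``tol_hold``.
    """
    if len(metrics) != 4:
        raise ValueError("a stimulus series has exactly 4 levels")
    if varying not in ("purity", "intensity"):
        raise ValueError("varying must be 'purity' or 'intensity'")
    lams = [m.lambda_d for m in metrics]
    hue_ok = all(l is not None for l in lams)
    spread = float(max(lams) - min(lams)) if hue_ok else float("inf")
    hue_ok = hue_ok and spread <= tol_hue
    sp = [m.spectral_purity for m in metrics]
    ii = [m.intensity for m in metrics]
    varied = sp if varying == "purity" else ii
    held = ii if varying == "purity" else sp
    monotone_ok = all(v is not None for v in varied) and \
        all(b > a for a, b in zip(varied, varied[1:]))
    held_spread = float("inf") if any(h is None for h in held) \
        else float(max(held) - min(held))
    hold_ok = held_spread <= tol_hold
    return SeriesReport(varying, hue_ok, monotone_ok, hold_ok,
                        spread, tuple(varied), held_spread)
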