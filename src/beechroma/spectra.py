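"""Spectral curves and their inputs.

Reading and writing delimited-text spectra, resampling onto a common
wavelength grid, visual-pigment sensitivity templates, and the packaged
D65 daylight illuminant.  Every quantity downstream of this module lives
on a shared 1 nm grid spanning the bee-visible range (300-700 nm by
default); illuminants are kept in photon (quantal) units throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._d65 import D65_RELATIVE_POWER, D65_WAVELENGTH_NM

__all__ = [
    "DEFAULT_GRID",
    "APIS_LAMBDA_MAX",
    "TRIGONA_LAMBDA_MAX",
    "SpectralCurve",
    "ReceptorSet",
    "read_spectra",
    "write_spectra",
    "resample",
    "sensitivity_template",
    "d65_illuminant",
    "flat_background",
]

#: Common working grid: 1 nm steps over the bee-visible range.
DEFAULT_GRID = np.arange(300.0, 700.0 + 0.5, 1.0)

#: Default receptor peak wavelengths (UV, blue, green), nm.
APIS_LAMBDA_MAX = (344.0, 436.0, 544.0)
TRIGONA_LAMBDA_MAX = (356.0, 428.0, 519.0)

_KINDS = ("reflectance", "irradiance", "sensitivity")

# White standards read slightly above 1; allow a little headroom.
_REFLECTANCE_MAX = 1.1


@dataclass(frozen=True)
class SpectralCurve:
    """A wavelength-sampled nonnegative function.

    Parameters
    ----------
    wavelengths
        Sample points in nm, strictly increasing.
    values
        Nonnegative samples: reflectance as a fraction (0-1 with
        white-standard headroom), irradiance in relative photon units,
        or sensitivity normalised to a maximum of 1.
    kind
        One of ``"reflectance"``, ``"irradiance"``, ``"sensitivity"``.
    name
        Optional label (e.g. the source column header).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str
    name: str = ""

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        if self.kind not in _KINDS:
            raise ValueError(f"unknown curve kind {self.kind!r}")
        if wl.ndim != 1 or wl.shape != vals.shape:
            raise ValueError("wavelengths and values must be equal-length 1-D arrays")
        if wl.size < 2:
            raise ValueError("a spectral curve needs at least two samples")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(vals < 0):
            raise ValueError(f"negative values in {self.kind} curve {self.name!r}")
        if self.kind == "reflectance" and np.any(vals > _REFLECTANCE_MAX):
            raise ValueError(
                f"reflectance {self.name!r} exceeds {_REFLECTANCE_MAX}; "
                "was the file in percent? pass unit_flag='percent'"
            )

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def __call__(self, grid) -> np.ndarray:
        """Linear interpolation at ``grid`` (must lie within the span)."""
        grid = np.asarray(grid, dtype=float)
        lo, hi = self.span
        if np.any(grid < lo) or np.any(grid > hi):
            raise ValueError(
                f"grid [{grid.min():g}, {grid.max():g}] extends beyond the "
                f"span [{lo:g}, {hi:g}] of curve {self.name!r}; no extrapolation"
            )
        return np.interp(grid, self.wavelengths, self.values)

    def scaled(self, factor: float) -> "SpectralCurve":
        return replace(self, values=self.values * factor)


def resample(curve: SpectralCurve, grid) -> SpectralCurve:
    """Linearly interpolate ``curve`` onto ``grid``; the kind is preserved.

    Raises ``ValueError`` if ``grid`` extends beyond the curve's span.
    """
    grid = np.asarray(grid, dtype=float)
    return SpectralCurve(grid, curve(grid), curve.kind, curve.name)


def read_spectra(path, unit_flag: str | None = None,
                 kind: str = "reflectance") -> list[SpectralCurve]:
    """Read spectra from a delimited text file.

    The file must have a header row; column 1 is the wavelength in nm
    (header starting with ``wavelength``) and each further column is one
    curve.  For reflectance input an explicit ``unit_flag`` of
    ``"fraction"`` or ``"percent"`` is required — units are never
    auto-detected, because a silent factor of 100 corrupts every
    downstream colour metric.
    """
    if kind == "reflectance":
        if unit_flag not in ("fraction", "percent"):
            raise ValueError(
                "unit_flag must be 'fraction' or 'percent' for reflectance input"
            )
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a wavelength column plus >=1 value column")
    first = str(df.columns[0]).strip().lower()
    if not first.startswith("wavelength"):
        raise ValueError(
            f"{path}: first column header must start with 'wavelength' "
            f"(got {df.columns[0]!r})"
        )
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    scale = 0.01 if unit_flag == "percent" else 1.0
    curves = []
    for col in df.columns[1:]:
        vals = df[col].to_numpy(dtype=float) * scale
        curves.append(SpectralCurve(wl, vals, kind, name=str(col)))
    return curves


def write_spectra(path, curves: list[SpectralCurve]) -> None:
    """Write curves sharing one grid to a CSV with a ``wavelength_nm`` column."""
    wl = curves[0].wavelengths
    for c in curves[1:]:
        if not np.array_equal(c.wavelengths, wl):
            raise ValueError("all curves must share one wavelength grid")
    data = {"wavelength_nm": wl}
    for i, c in enumerate(curves):
        data[c.name or f"curve_{i + 1}"] = c.values
    pd.DataFrame(data).to_csv(path, index=False)


def sensitivity_template(lambda_max: float, grid=None) -> SpectralCurve:
    """A1 visual-pigment absorbance template peaking at ``lambda_max``.

    Govardovskii et al. (2000) rhodopsin nomogram: a log-normal-like
    alpha band plus a Gaussian beta band, max-normalised to 1.  Used as
    the stand-in for measured receptor sensitivity curves.
    """
    if not (300.0 <= lambda_max <= 650.0):
        raise ValueError(f"lambda_max {lambda_max} nm outside the supported 300-650 nm")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)

    x = lambda_max / grid
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    lam_beta = 189.0 + 0.315 * lambda_max
    b_beta = -40.5 + 0.195 * lambda_max
    beta = 0.26 * np.exp(-(((grid - lam_beta) / b_beta) ** 2))

    vals = alpha + beta
    vals = vals / vals.max()
    return SpectralCurve(grid, vals, "sensitivity", name=f"A1_{lambda_max:g}nm")


def d65_illuminant(grid=None) -> SpectralCurve:
    """Standard daylight D65 in relative photon units on ``grid``.

    The packaged energy table is converted once to quantal units
    (photon flux proportional to energy x wavelength) and linearly
    resampled; grids outside 300-830 nm are refused.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    energy = SpectralCurve(D65_WAVELENGTH_NM, D65_RELATIVE_POWER,
                           "irradiance", name="D65_energy")
    photon = energy(grid) * grid / 100.0
    return SpectralCurve(grid, photon, "irradiance", name="D65")


def flat_background(reflectance: float = 0.2, grid=None) -> SpectralCurve:
    """Spectrally flat grey background (default reflectance 0.2)."""
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    return SpectralCurve(grid, np.full(grid.shape, float(reflectance)),
                         "reflectance", name=f"grey_{reflectance:g}")


@dataclass(frozen=True)
class ReceptorSet:
    """UV, blue and green receptor sensitivities of a trichromatic bee."""

    uv: SpectralCurve
    blue: SpectralCurve
    green: SpectralCurve
    lambda_max: tuple[float, float, float] = field(default=(np.nan,) * 3)
    species_label: str = ""

    def __post_init__(self):
        for c in (self.uv, self.blue, self.green):
            if c.kind != "sensitivity":
                raise ValueError(f"receptor curve {c.name!r} must have kind 'sensitivity'")
            if not np.isclose(c.values.max(), 1.0, atol=1e-9):
                raise ValueError(f"receptor curve {c.name!r} must be max-normalised to 1")
        lm = self.lambda_max
        if np.all(np.isfinite(lm)) and not (lm[0] < lm[1] < lm[2]):
            raise ValueError("lambda_max must satisfy uv < blue < green")

    @classmethod
    def from_lambda_max(cls, lambda_max=APIS_LAMBDA_MAX, grid=None,
                        species_label: str = "apis") -> "ReceptorSet":
        """Template-generated receptor set from three peak wavelengths."""
        uv, blue, green = (sensitivity_template(lm, grid) for lm in lambda_max)
        return cls(uv, blue, green, tuple(float(v) for v in lambda_max), species_label)

    def curves(self) -> tuple[SpectralCurve, SpectralCurve, SpectralCurve]:
        return (self.uv, self.blue, self.green)
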