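"""SIF retrieval algorithms: FLD, 3FLD and the spectral fitting method.

All three estimate the fluorescence radiance at the bottom of a telluric
oxygen band from a paired downwelling spectrum ``E`` and upwelling
radiance ``L``, exploiting the in-band/out-of-band contrast:

* **FLD** — two channels (band bottom ``in`` and one left shoulder
  ``out``), assuming constant reflectance and fluorescence across them:
  ``F = (E_out L_in - E_in L_out) / (E_out - E_in)``.
* **3FLD** — left and right shoulders combined with interpolation
  weights ``w_left = (lam_right - lam_in) / (lam_right - lam_left)`` and
  ``w_right = 1 - w_left`` applied to both E and L before the FLD
  formula; exact for linearly varying reflectance (equal shoulder
  continuum) and constant fluorescence.
* **SFM** — linear least squares on the forward model
  ``L(lam) = E(lam) r(lam) / pi + F(lam)`` over all samples in the
  window, with ``r`` and ``F`` polynomials in ``lam - lam_in`` of the
  window's degrees; returns F evaluated at the band bottom.

``E`` may be tagged irradiance (divided by pi internally, i.e. treated
as the radiance of a perfectly Lambertian unit-reflectance panel) or
panel-equivalent radiance (used as is).  FLD/3FLD estimates are
invariant to that constant scale.  Retrieved values may be negative
under noise and are returned unclipped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .spectra import Spectrum, nearest_index

__all__ = [
    "RetrievalWindow",
    "RetrievalResult",
    "RetrievalStats",
    "fld",
    "three_fld",
    "sfm",
    "retrieve",
    "retrieve_many",
    "retrieve_ensemble",
    "bundled_windows",
    "candidate_windows",
    "selected_window",
]

logger = logging.getLogger(__name__)

ALGORITHMS = ("FLD", "3FLD", "SFM")
BANDS = ("O2A", "O2B")


@dataclass(frozen=True)
class RetrievalWindow:
    """One concrete retrieval parameterization.

    `lambda_in` is the band-bottom anchor; `lambda_left` the left
    shoulder (FLD/3FLD) or left window bound (SFM); `lambda_right` the
    right shoulder/bound (absent for FLD).  Polynomial degrees apply to
    SFM only, with the reflectance degree at least the fluorescence
    degree.
    """

    algorithm: str
    band: str
    lambda_in: float
    lambda_left: float
    lambda_right: float | None = None
    degree_r: int | None = None
    degree_f: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.band not in BANDS:
            raise ValueError(f"band must be one of {BANDS}")
        if not self.lambda_left < self.lambda_in:
            raise ValueError("lambda_left must be shorter than lambda_in")
        if self.algorithm != "FLD":
            if self.lambda_right is None:
                raise ValueError(f"{self.algorithm} requires lambda_right")
            if not self.lambda_in < self.lambda_right:
                raise ValueError("lambda_right must be longer than lambda_in")
        if self.algorithm == "SFM":
            if self.degree_r is None or self.degree_f is None:
                raise ValueError("SFM requires polynomial degrees")
            if self.degree_r < self.degree_f:
                raise ValueError("degree_r must be >= degree_f")
        elif self.degree_r is not None or self.degree_f is not None:
            raise ValueError("polynomial degrees apply to SFM only")


@dataclass(frozen=True)
class RetrievalResult:
    algorithm: str
    band: str
    f_value: float  # retrieved fluorescence radiance at lambda_in
    window: RetrievalWindow
    coefficients: np.ndarray | None = None  # SFM polynomial coefficients


@dataclass(frozen=True)
class RetrievalStats:
    """Ensemble statistics of retrieved fluorescence."""

    mean: float
    sd: float
    bias: float  # mean - injected truth
    truth: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0 or self.n < 1:
            raise ValueError("sd must be >= 0 and n >= 1")


def _panel_values(E: Spectrum) -> np.ndarray:
    if E.unit == "irradiance":
        return E.values / np.pi
    if E.unit == "radiance":
        return E.values
    raise ValueError("E must be tagged 'irradiance' or 'radiance'")


def _snap(wavelengths: np.ndarray, target: float) -> int:
    """Snap an anchor to the nearest grid sample (ties toward shorter).

    The snap distance must stay below half the local sample spacing.
    """
    i = nearest_index(wavelengths, target)
    spacing = np.diff(wavelengths).max()
    dist = abs(wavelengths[i] - target)
    if dist >= spacing / 2 - 1e-9:
        raise ValueError(
            f"anchor {target} nm falls {dist:.3f} nm from the nearest sample"
        )
    logger.debug("anchor %.3f nm snapped to %.3f nm (%.3f nm away)", target, wavelengths[i], dist)
    return i


def _check_pair(E: Spectrum, L: Spectrum) -> None:
    if not np.array_equal(E.wavelengths, L.wavelengths):
        raise ValueError("E and L must share the same wavelength grid")
    if L.unit != "radiance":
        raise ValueError("L must be tagged 'radiance'")


def _fld_values(e_in, e_out, l_in, l_out):
    denom = e_out - e_in
    if np.any(np.abs(denom) <= 1e-12 * np.abs(e_out)):
        raise ValueError("degenerate band: no absorption contrast between channels")
    return (e_out * l_in - e_in * l_out) / denom


def fld(E: Spectrum, L: Spectrum, window: RetrievalWindow) -> RetrievalResult:
    """Two-channel FLD with a single left shoulder."""
    _check_pair(E, L)
    wl = E.wavelengths
    i_in, i_out = _snap(wl, window.lambda_in), _snap(wl, window.lambda_left)
    e = _panel_values(E)
    f = _fld_values(e[i_in], e[i_out], L.values[i_in], L.values[i_out])
    return RetrievalResult(window.algorithm, window.band, float(f), window)


def three_fld_weights(window: RetrievalWindow) -> tuple[float, float]:
    """Interpolation weights of the left/right shoulders; they sum to 1."""
    span = window.lambda_right - window.lambda_left
    w_left = (window.lambda_right - window.lambda_in) / span
    return w_left, 1.0 - w_left


def three_fld(E: Spectrum, L: Spectrum, window: RetrievalWindow) -> RetrievalResult:
    """Three-channel FLD: shoulders interpolated to the band bottom."""
    _check_pair(E, L)
    wl = E.wavelengths
    i_in = _snap(wl, window.lambda_in)
    i_l = _snap(wl, window.lambda_left)
    i_r = _snap(wl, window.lambda_right)
    # weights from the actual (snapped) wavelengths
    span = wl[i_r] - wl[i_l]
    w_l = (wl[i_r] - wl[i_in]) / span
    w_r = 1.0 - w_l
    e = _panel_values(E)
    e_out = w_l * e[i_l] + w_r * e[i_r]
    l_out = w_l * L.values[i_l] + w_r * L.values[i_r]
    f = _fld_values(e[i_in], e_out, L.values[i_in], l_out)
    return RetrievalResult(window.algorithm, window.band, float(f), window)


def _sfm_design(e_panel: np.ndarray, dlam: np.ndarray, degree_r: int, degree_f: int) -> np.ndarray:
    """Design matrix: reflectance columns e*(dlam^j), fluorescence columns dlam^k."""
    cols = [e_panel * dlam**j for j in range(degree_r + 1)]
    cols += [dlam**k for k in range(degree_f + 1)]
    return np.column_stack(cols)


def sfm(E: Spectrum, L: Spectrum, window: RetrievalWindow) -> RetrievalResult:
    """Spectral fitting method: least-squares polynomial fit over the window.

    Wavelengths are centered on ``lambda_in`` before building the
    polynomial terms, so the fluorescence constant coefficient is the
    retrieved value at the band bottom.
    """
    _check_pair(E, L)
    wl = E.wavelengths
    mask = (wl >= window.lambda_left) & (wl <= window.lambda_right)
    n_coef = window.degree_r + window.degree_f + 2
    if mask.sum() < n_coef:
        raise ValueError(
            f"window contains {int(mask.sum())} samples, fewer than {n_coef} coefficients"
        )
    dlam = wl[mask] - window.lambda_in
    e_panel = _panel_values(E)[mask]
    design = _sfm_design(e_panel, dlam, window.degree_r, window.degree_f)
    coef, _, rank, _ = np.linalg.lstsq(design, L.values[mask], rcond=None)
    if rank < n_coef:
        warnings.warn(
            "rank-deficient SFM design (collinear reflectance/fluorescence terms)",
            stacklevel=2,
        )
    f_poly = coef[window.degree_r + 1 :]
    d_in = wl[_snap(wl, window.lambda_in)] - window.lambda_in
    f = float(np.polyval(f_poly[::-1], d_in))
    return RetrievalResult(window.algorithm, window.band, f, window, coefficients=coef)


_DISPATCH = {"FLD": fld, "3FLD": three_fld, "SFM": sfm}


def retrieve(E: Spectrum, L: Spectrum, window: RetrievalWindow) -> RetrievalResult:
    """Apply the window's algorithm to one spectrum pair."""
    return _DISPATCH[window.algorithm](E, L, window)


def retrieve_many(
    wavelengths: np.ndarray,
    E_values: np.ndarray,
    L_values: np.ndarray,
    window: RetrievalWindow,
    e_unit: str = "irradiance",
) -> np.ndarray:
    """Vectorized retrieval over paired realization matrices (n, n_wl).

    Realization i of E is paired with realization i of L.  FLD/3FLD are
    evaluated in closed form across realizations; SFM solves one small
    least-squares problem per realization.
    """
    E_values = np.atleast_2d(E_values)
    L_values = np.atleast_2d(L_values)
    if E_values.shape != L_values.shape:
        raise ValueError("E and L ensembles must have the same shape")
    e_all = E_values / np.pi if e_unit == "irradiance" else E_values
    wl = np.asarray(wavelengths, dtype=float)

    if window.algorithm == "FLD":
        i_in, i_out = _snap(wl, window.lambda_in), _snap(wl, window.lambda_left)
        return _fld_values(e_all[:, i_in], e_all[:, i_out], L_values[:, i_in], L_values[:, i_out])
    if window.algorithm == "3FLD":
        i_in = _snap(wl, window.lambda_in)
        i_l, i_r = _snap(wl, window.lambda_left), _snap(wl, window.lambda_right)
        w_l = (wl[i_r] - wl[i_in]) / (wl[i_r] - wl[i_l])
        w_r = 1.0 - w_l
        e_out = w_l * e_all[:, i_l] + w_r * e_all[:, i_r]
        l_out = w_l * L_values[:, i_l] + w_r * L_values[:, i_r]
        return _fld_values(e_all[:, i_in], e_out, L_values[:, i_in], l_out)

    mask = (wl >= window.lambda_left) & (wl <= window.lambda_right)
    dlam = wl[mask] - window.lambda_in
    d_in = wl[_snap(wl, window.lambda_in)] - window.lambda_in
    out = np.empty(E_values.shape[0])
    for i in range(E_values.shape[0]):
        design = _sfm_design(e_all[i, mask], dlam, window.degree_r, window.degree_f)
        coef = np.linalg.lstsq(design, L_values[i, mask], rcond=None)[0]
        out[i] = np.polyval(coef[window.degree_r + 1 :][::-1], d_in)
    return out


def retrieve_ensemble(
    E_set,
    L_set,
    window: RetrievalWindow,
    truth: float,
    wavelengths: np.ndarray | None = None,
    e_unit: str = "irradiance",
) -> RetrievalStats:
    """Mean/sd/bias of retrieved fluorescence over a paired noise ensemble.

    `E_set`/`L_set` are either sequences of :class:`Spectrum` or
    realization matrices (n, n_wl) with `wavelengths` given explicitly.
    """
    if wavelengths is None:
        E_list, L_list = list(E_set), list(L_set)
        if len(E_list) != len(L_list):
            raise ValueError("E and L ensembles must have the same size")
        wavelengths = E_list[0].wavelengths
        e_unit = E_list[0].unit
        E_set = np.vstack([s.values for s in E_list])
        L_set = np.vstack([s.values for s in L_list])
    values = retrieve_many(wavelengths, E_set, L_set, window, e_unit=e_unit)
    n = values.size
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    return RetrievalStats(mean=mean, sd=sd, bias=mean - truth, truth=truth, n=n)


# ---------------------------------------------------------------------------
# bundled window tables


def _windows_frame() -> pd.DataFrame:
    with resources.files("canopysif.data").joinpath("windows.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


def _row_to_window(row) -> RetrievalWindow:
    return RetrievalWindow(
        algorithm=row["algorithm"],
        band=row["band"],
        lambda_in=float(row["lambda_in"]),
        lambda_left=float(row["lambda_left"]),
        lambda_right=None if pd.isna(row["lambda_right"]) else float(row["lambda_right"]),
        degree_r=None if pd.isna(row["degree_r"]) else int(row["degree_r"]),
        degree_f=None if pd.isna(row["degree_f"]) else int(row["degree_f"]),
        label=row["label"],
    )


def bundled_windows() -> list[RetrievalWindow]:
    """All bundled windows (candidate sets and operational selections)."""
    return [_row_to_window(r) for _, r in _windows_frame().iterrows()]


def candidate_windows(band: str, algorithm: str) -> list[RetrievalWindow]:
    """The comparison candidates for one band and algorithm."""
    df = _windows_frame()
    df = df[(df["set"] == "candidate") & (df["band"] == band) & (df["algorithm"] == algorithm)]
    if df.empty:
        raise KeyError(f"no candidate windows for {band}/{algorithm}")
    return [_row_to_window(r) for _, r in df.iterrows()]


def selected_window(band: str, algorithm: str) -> RetrievalWindow:
    """The operationally selected window for one band and algorithm."""
    df = _windows_frame()
    df = df[(df["set"] == "selected") & (df["band"] == band) & (df["algorithm"] == algorithm)]
    if df.empty:
        raise KeyError(f"no selected window for {band}/{algorithm}")
    return _row_to_window(df.iloc[0])
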