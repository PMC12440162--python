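"""VAR fitting, partial directed coherence spectra, and information flow.

The directed influence between two position time-series is estimated in the
frequency domain.  A vector autoregressive model

    y(t) = A_1 y(t-1) + ... + A_p y(t-p) + w(t),   w ~ (0, Sigma_w)

is fitted to each mean-removed bivariate series by conditional least squares.
From the fitted coefficients the spectral coefficient matrix

    Abar(f) = I - sum_m A_m exp(-i 2 pi f m / fs)

yields, for each ordered direction j -> i, the squared information partial
directed coherence

    iPDC^2_{i<-j}(f) = |Abar_ij(f)|^2 / ( Sigma_ii * abar_j(f)^H Sigma_w^{-1} abar_j(f) )

where abar_j is column j of Abar.  This quantity lies in [0, 1] (tight, by
Cauchy-Schwarz in the Sigma_w^{-1} inner product) and reduces to the squared
generalized PDC when Sigma_w is diagonal.  Classic PDC (column-norm
normalization) and generalized PDC are available behind the ``variant``
switch; ``"info"`` is the default.

The scalar influence measure integrates the spectrum into information flow

    I_flow = -(1/fs) * integral_0^{fs/2} log2(1 - iPDC^2(f)) df     [bits]

the mutual-information rate between the past of the source and the present
of the target implied by the fitted model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .proximity import ProximityInteraction, build_bivariate_series

VARIANTS = ("euc", "diag", "info")

_CLIP = 1.0 - 1e-12          # keep log2(1 - v) finite at the boundary
_OVERSHOOT_TOL = 1e-6        # spectrum values above 1 + tol are a formula/fit error


class InfluenceFitError(RuntimeError):
    """All interactions of a focal bee failed to produce a VAR fit."""

    def __init__(self, message: str, diagnostics: list[str]):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass
class VarModel:
    """Fitted VAR(p): coefficient matrices and innovation covariance."""

    order: int
    coef: np.ndarray          # (p, k, k); coef[m-1] is A_m
    sigma: np.ndarray         # (k, k) innovation covariance
    n_obs: int                # series length
    n_eff: int                # regression sample size (n_obs - order)

    @property
    def k(self) -> int:
        return self.coef.shape[1]

    def companion_spectral_radius(self) -> float:
        p, k = self.order, self.k
        top = np.hstack(list(self.coef))
        if p == 1:
            comp = top
        else:
            comp = np.vstack([top, np.hstack([np.eye(k * (p - 1)), np.zeros((k * (p - 1), k))])])
        return float(np.max(np.abs(np.linalg.eigvals(comp))))


@dataclass
class IpdcSpectrum:
    """Directional squared-PDC values on a frequency grid spanning [0, fs/2].

    ``values[i, j, :]`` is the direction j -> i.
    """

    freqs: np.ndarray
    values: np.ndarray
    fs: float
    variant: str = "info"

    def direction(self, src: int, dst: int) -> np.ndarray:
        """Spectrum of the ordered direction src -> dst (0-based channels)."""
        return self.values[dst, src, :]


def _lag_design(x: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Response Y (T-p, k) and lagged design Z (T-p, k*p) for conditional LS."""
    T, k = x.shape
    Y = x[p:]
    Z = np.hstack([x[p - m:T - m] for m in range(1, p + 1)])
    return Y, Z


def fit_var(series, order: int | str = "aic", p_max: int = 3) -> VarModel:
    """Conditional least-squares VAR fit on the mean-removed series.

    Parameters
    ----------
    series : array (n, k), or a pair of equal-length 1-D arrays
        The raw series; the mean of each channel is removed before fitting.
    order : int or "aic"
        Explicit lag order, or automatic selection minimizing the
        multivariate AIC  ln det(Sigma_ML) + 2 k^2 p / T  over p in
        {1..p_max}, compared on a common effective sample.
    p_max : int
        Cap for automatic order selection (small by design: the pipeline's
        30-sample windows identify at most a handful of lags).

    Notes
    -----
    The innovation covariance uses the degrees-of-freedom corrected
    denominator  T_eff - k*p  (T_eff = n - p regression equations, k*p
    regressors per equation, no intercept because the series is centered).

    Raises
    ------
    ValueError
        For series too short for the requested order, or (near-)constant
        series that make the regression singular.
    """
    if isinstance(series, (tuple, list)):
        arrs = [np.asarray(s, dtype=float).ravel() for s in series]
        if len({len(a) for a in arrs}) != 1:
            raise ValueError("paired series must have equal lengths")
        x = np.column_stack(arrs)
    else:
        x = np.asarray(series, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    n, k = x.shape
    x = x - x.mean(axis=0)

    if np.any(x.std(axis=0) < 1e-12):
        raise ValueError("constant series: VAR regression is singular")

    if order == "aic":
        best_p, best_aic = None, np.inf
        cap = min(p_max, (n - 1) // (k + 1))
        if cap < 1:
            raise ValueError(f"series of length {n} too short for any VAR order")
        # compare orders on the common sample starting at lag p_max
        for p in range(1, cap + 1):
            xs = x[cap - p:]
            Y, Z = _lag_design(xs, p)
            B, *_ = np.linalg.lstsq(Z, Y, rcond=None)
            resid = Y - Z @ B
            T = Y.shape[0]
            sig_ml = resid.T @ resid / T
            sign, logdet = np.linalg.slogdet(sig_ml)
            if sign <= 0:
                continue
            aic = logdet + 2.0 * (k * k * p) / T
            if aic < best_aic:
                best_aic, best_p = aic, p
        if best_p is None:
            raise ValueError("no VAR order produced a non-singular fit")
        p = best_p
    else:
        p = int(order)
        if p < 1:
            raise ValueError("order must be >= 1")

    if n - p < k * p + 2:
        raise ValueError(f"series of length {n} too short for VAR({p})")

    Y, Z = _lag_design(x, p)
    B, _, rank, _ = np.linalg.lstsq(Z, Y, rcond=None)
    if rank < Z.shape[1]:
        raise ValueError("rank-deficient VAR regression (degenerate series)")
    resid = Y - Z @ B
    T = Y.shape[0]
    dof = max(T - k * p, 1)
    sigma = resid.T @ resid / dof
    coef = np.stack([B[m * k:(m + 1) * k].T for m in range(p)])
    return VarModel(order=p, coef=coef, sigma=sigma, n_obs=n, n_eff=T)


def spectral_matrix(model: VarModel, freqs: np.ndarray) -> np.ndarray:
    """Abar(f) = I - sum_m A_m exp(-i 2 pi f m / fs) for each f; shape (F, k, k).

    Frequencies are interpreted in the same units as the model's sampling
    rate; the caller supplies f/fs-scaled grids via :func:`ipdc_spectrum`.
    """
    k = model.k
    F = len(freqs)
    Ab = np.tile(np.eye(k, dtype=complex), (F, 1, 1))
    for m in range(1, model.order + 1):
        phase = np.exp(-2j * np.pi * freqs * m)[:, None, None]
        Ab -= model.coef[m - 1][None, :, :] * phase
    return Ab


def ipdc_spectrum(model: VarModel, n_freqs: int = 128, fs: float = 1.0,
                  variant: str = "info") -> IpdcSpectrum:
    """Squared partial-directed-coherence spectrum on a uniform grid over [0, fs/2].

    ``variant``: ``"euc"`` (classic PDC, column-norm normalization),
    ``"diag"`` (generalized PDC, innovation-variance weighting), or
    ``"info"`` (information PDC, full innovation-covariance weighting;
    default).
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    if n_freqs < 2:
        raise ValueError("n_freqs must be at least 2")
    sigma = model.sigma
    cond = np.linalg.cond(sigma)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError("singular innovation covariance")
    freqs = np.linspace(0.0, fs / 2.0, n_freqs)
    Ab = spectral_matrix(model, freqs / fs)        # (F, k, k)
    mag2 = np.abs(Ab) ** 2
    k = model.k
    if variant == "euc":
        denom = mag2.sum(axis=1)                   # column norms, (F, k)
        vals = mag2 / denom[:, None, :]
    elif variant == "diag":
        d = np.diag(sigma)
        w = mag2 / d[None, :, None]                # |A_ij|^2 / sigma_ii
        denom = w.sum(axis=1)
        vals = w / denom[:, None, :]
    else:  # info
        sig_inv = np.linalg.inv(sigma)
        # abar_j^H Sigma^-1 abar_j for each f and column j
        denom = np.real(np.einsum("fij,ik,fkj->fj", Ab.conj(), sig_inv, Ab))
        d = np.diag(sigma)
        vals = mag2 / (d[None, :, None] * denom[:, None, :])
    values = np.transpose(vals, (1, 2, 0))         # (k, k, F)
    return IpdcSpectrum(freqs=freqs, values=values, fs=fs, variant=variant)


def information_flow(spectrum: IpdcSpectrum | np.ndarray,
                     direction: tuple[int, int] | None = None,
                     freqs: np.ndarray | None = None,
                     fs: float | None = None) -> float:
    """Integrate a directional spectrum into information flow, in bits.

    I_flow = -(1/fs) * trapezoid of log2(1 - v) over the frequency grid.
    Values are clipped to 1 - 1e-12 before the logarithm; values exceeding
    1 beyond numerical tolerance indicate an invalid spectrum and raise.

    Accepts either an :class:`IpdcSpectrum` plus a ``direction=(src, dst)``,
    or a raw value array with explicit ``freqs`` and ``fs``.
    """
    if isinstance(spectrum, IpdcSpectrum):
        if direction is None:
            raise ValueError("direction=(src, dst) required with an IpdcSpectrum")
        v = spectrum.direction(*direction)
        freqs = spectrum.freqs
        fs = spectrum.fs
    else:
        v = np.asarray(spectrum, dtype=float)
        if freqs is None or fs is None:
            raise ValueError("freqs and fs required with a raw value array")
    if np.any(v > 1.0 + _OVERSHOOT_TOL) or np.any(v < -_OVERSHOOT_TOL):
        raise ValueError("spectrum values outside [0, 1]: invalid spectrum")
    v = np.clip(v, 0.0, _CLIP)
    return float(-np.trapezoid(np.log2(1.0 - v), freqs) / fs)


@dataclass(frozen=True)
class InfluenceSettings:
    order: int | str = "aic"
    p_max: int = 3
    n_freqs: int = 128
    fs: float = 1.0
    variant: str = "info"
    difference: bool = False   # optionally first-difference the series


@dataclass
class InfluenceResult:
    """Per-bee bidirectional information flow with per-axis components."""

    bee_id: object
    i_flow_out: float           # focal -> neighbor, bits
    i_flow_in: float            # neighbor -> focal, bits
    out_by_axis: dict[str, float]
    in_by_axis: dict[str, float]
    n_interactions: int
    diagnostics: list[str] = field(default_factory=list)


def social_influence(focal_id, interactions: list[ProximityInteraction],
                     settings: InfluenceSettings = InfluenceSettings()) -> InfluenceResult:
    """Average iPDC spectra over a focal bee's interactions and integrate.

    For each interaction and each coordinate axis a VAR is fitted to the
    (focal, neighbor) pair and both directional spectra are computed on a
    shared grid.  Spectra are averaged pointwise across interactions per
    axis, each averaged spectrum is integrated into I_flow, and the X and Y
    results are averaged into the reported per-direction flow.
    """
    if not interactions:
        raise ValueError(f"no interactions supplied for bee {focal_id!r}")
    F = settings.n_freqs
    sums = {ax: {"out": np.zeros(F), "in": np.zeros(F)} for ax in ("X", "Y")}
    counts = {ax: 0 for ax in ("X", "Y")}
    diagnostics: list[str] = []
    freqs = None
    for it in interactions:
        for ax in ("X", "Y"):
            focal, nb = build_bivariate_series(it, ax)
            if settings.difference:
                focal, nb = np.diff(focal), np.diff(nb)
            try:
                model = fit_var((focal, nb), order=settings.order, p_max=settings.p_max)
                spec = ipdc_spectrum(model, n_freqs=F, fs=settings.fs, variant=settings.variant)
            except ValueError as exc:
                diagnostics.append(
                    f"interaction {it.focal_id!r}->{it.neighbor_id!r} "
                    f"[{it.start_frame},{it.end_frame}] axis {ax}: {exc}")
                continue
            sums[ax]["out"] += spec.direction(0, 1)
            sums[ax]["in"] += spec.direction(1, 0)
            counts[ax] += 1
            freqs = spec.freqs
    if all(c == 0 for c in counts.values()):
        raise InfluenceFitError(
            f"all interactions failed to fit for bee {focal_id!r}", diagnostics)
    out_ax, in_ax = {}, {}
    for ax in ("X", "Y"):
        if counts[ax] == 0:
            continue
        out_ax[ax] = information_flow(sums[ax]["out"] / counts[ax], freqs=freqs, fs=settings.fs)
        in_ax[ax] = information_flow(sums[ax]["in"] / counts[ax], freqs=freqs, fs=settings.fs)
    return InfluenceResult(
        bee_id=focal_id,
        i_flow_out=float(np.mean(list(out_ax.values()))),
        i_flow_in=float(np.mean(list(in_ax.values()))),
        out_by_axis=out_ax,
        in_by_axis=in_ax,
        n_interactions=len(interactions),
        diagnostics=diagnostics,
    )


def social_influence_table(interactions: dict[object, list[ProximityInteraction]],
                           settings: InfluenceSettings = InfluenceSettings()):
    """Run :func:`social_influence` for every focal bee with interactions.

    Returns (DataFrame, diagnostics); bees whose fits all failed appear only
    in the diagnostics.
    """
    import pandas as pd

    rows, notes = [], []
    for focal in sorted(interactions, key=str):
        its = interactions[focal]
        if not its:
            continue
        try:
            r = social_influence(focal, its, settings)
        except InfluenceFitError as exc:
            notes.extend(exc.diagnostics)
            notes.append(str(exc))
            continue
        notes.extend(r.diagnostics)
        rows.append({
            "bee_id": r.bee_id,
            "i_flow_out_bits": r.i_flow_out,
            "i_flow_in_bits": r.i_flow_in,
            "i_flow_out_x": r.out_by_axis.get("X", np.nan),
            "i_flow_out_y": r.out_by_axis.get("Y", np.nan),
            "i_flow_in_x": r.in_by_axis.get("X", np.nan),
            "i_flow_in_y": r.in_by_axis.get("Y", np.nan),
            "n_interactions": r.n_interactions,
        })
    return pd.DataFrame(rows), notes
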