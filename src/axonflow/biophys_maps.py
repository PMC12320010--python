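"""Per-voxel biophysical scalar maps used as flow-model context features.

Seven scalars are fitted per voxel and concatenated to the learned context:
NODDI-style intracellular volume fraction, isotropic fraction and
orientation dispersion (reduced Watson stick+zeppelin+ball variant), DTI
fractional anisotropy and mean diffusivity, and the two-pool MT bound-pool
fraction and exchange rate. The module also carries the closed-form
volume-fraction g-ratio g = 1/sqrt(1 + MVF/AVF) and the analytic minimum
detectable axon diameter for single diffusion encoding.

The fitters follow the scikit-learn estimator protocol (`fit` validates the
protocol, `transform` maps an (n_voxels, n_meas) signal block to per-voxel
parameters); module-level functions wrap them for single voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import forward_sim
from .exceptions import DesignMatrixError, ParameterError
from .forward_sim import TissueConstants
from .protocols import GAMMA_H, DiffusionProtocol, MTProtocol


@dataclass
class BiophysMaps:
    """Per-voxel fitted scalars; each field is an array of length n_voxels."""

    icvf: np.ndarray
    iso: np.ndarray
    od: np.ndarray
    fa: np.ndarray
    md: np.ndarray
    f_bound: np.ndarray
    k_exchange: np.ndarray

    FIELDS = ("icvf", "iso", "od", "fa", "md", "f_bound", "k_exchange")

    def context_matrix(self) -> np.ndarray:
        """(n_voxels, 7) matrix in the canonical field order."""
        return np.column_stack([getattr(self, f) for f in self.FIELDS])

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "BiophysMaps":
        m = np.atleast_2d(m)
        return cls(*[m[:, i] for i in range(7)])


# ---------------------------------------------------------------------------
# DTI


def _dti_design(protocol: DiffusionProtocol, mask) -> np.ndarray:
    b = protocol.bvals[mask] * 1e-3  # ms/um^2 so diffusivities come out um^2/ms
    g = protocol.directions[mask]
    return np.column_stack([
        np.ones_like(b),
        -b * g[:, 0] ** 2, -b * g[:, 1] ** 2, -b * g[:, 2] ** 2,
        -2 * b * g[:, 0] * g[:, 1], -2 * b * g[:, 0] * g[:, 2],
        -2 * b * g[:, 1] * g[:, 2]])


class DTIFitter(BaseEstimator, TransformerMixin):
    """Weighted log-linear diffusion-tensor fit.

    Only measurements with b <= ``b_max`` (s/mm^2) plus the b=0 rows enter
    the fit: the log-linear tensor representation is only meaningful in the
    low-b regime of the two-shell protocol. Weights are the squared signals
    (first-order propagation of log-domain noise).
    """

    def __init__(self, protocol: DiffusionProtocol | None = None,
                 b_max: float = 4000.0):
        self.protocol = protocol
        self.b_max = b_max

    def fit(self, X=None, y=None):
        if self.protocol is None:
            raise ParameterError("a DiffusionProtocol is required")
        mask = self.protocol.bvals <= self.b_max
        if np.sum(self.protocol.bvals[mask] > 0) < 6 or \
                not np.any(self.protocol.bvals[mask] == 0):
            raise DesignMatrixError(
                "DTI needs >= 6 diffusion-weighted directions and >= 1 b=0 "
                "measurement below b_max")
        A = _dti_design(self.protocol, mask)
        if np.linalg.matrix_rank(A) < 7:
            raise DesignMatrixError("rank-deficient DTI design matrix")
        self.mask_ = mask
        self.design_ = A
        return self

    def transform(self, X) -> np.ndarray:
        """(n_voxels, n_meas) signals -> (n_voxels, 2) [fa, md] (um^2/ms)."""
        check_is_fitted(self)
        X = np.atleast_2d(np.asarray(X, float))
        out = np.empty((X.shape[0], 2))
        self.eigenvectors_ = np.empty((X.shape[0], 3))
        for i, x in enumerate(X):
            fa, md, evals, evecs = self._fit_one(x)
            out[i] = fa, md
            self.eigenvectors_[i] = evecs[:, np.argmax(evals)]
        return out

    def _fit_one(self, x):
        s = np.clip(x[self.mask_], 1e-8, None)
        w = s ** 2
        A = self.design_
        coef, *_ = np.linalg.lstsq(A * w[:, None], np.log(s) * w, rcond=None)
        D = np.array([[coef[1], coef[4], coef[5]],
                      [coef[4], coef[2], coef[6]],
                      [coef[5], coef[6], coef[3]]])
        evals, evecs = np.linalg.eigh(D)
        evals = np.clip(evals, 0.0, None)  # negative eigenvalues clipped
        md = evals.mean()
        denom = np.sqrt((evals ** 2).sum())
        fa = 0.0 if denom == 0 else float(
            np.sqrt(1.5 * ((evals - md) ** 2).sum()) / denom)
        return fa, float(md), evals, evecs


def fit_dti(diffusion_signal, protocol: DiffusionProtocol, b_max=4000.0):
    """Single-voxel convenience wrapper: returns (fa, md, tensor_evals)."""
    f = DTIFitter(protocol, b_max).fit()
    fa_md = f.transform(np.atleast_2d(diffusion_signal))[0]
    fa, md, evals, _ = f._fit_one(np.asarray(diffusion_signal, float))
    return float(fa_md[0]), float(fa_md[1]), evals


# ---------------------------------------------------------------------------
# two-pool MT


class TwoPoolMTFitter(BaseEstimator, TransformerMixin):
    """Nonlinear least-squares inversion of the two-pool MT-SPGR model.

    Fits (F, k) per voxel with box constraints F in (0, 0.5], k in (0, 100]
    1/s, multistarting from four fixed initializations. Non-converged voxels
    get NaN sentinels; voxels whose fit pins F at the lower bound (no
    saturation information) are flagged.
    """

    STARTS = ((0.05, 10.0), (0.15, 20.0), (0.30, 20.0), (0.10, 50.0))
    BOUNDS = ((1e-4, 0.5), (1e-2, 100.0))

    def __init__(self, protocol: MTProtocol | None = None,
                 consts: TissueConstants | None = None):
        self.protocol = protocol
        self.consts = consts

    def fit(self, X=None, y=None):
        if self.protocol is None:
            raise ParameterError("an MTProtocol is required")
        if self.protocol.n_measurements < 4:
            raise ParameterError("two-pool fit needs >= 4 (angle, offset) points")
        self.consts_ = self.consts or TissueConstants()
        return self

    def _model(self, F, k):
        c = replace(self.consts_,
                    mt_pool=replace(self.consts_.mt_pool, k_exchange=k))
        return forward_sim.mt_spgr_signal(float(F), self.protocol, c)

    def transform(self, X) -> np.ndarray:
        """(n_voxels, n_meas) MT signals -> (n_voxels, 2) [F, k]."""
        check_is_fitted(self)
        X = np.atleast_2d(np.asarray(X, float))
        out = np.full((X.shape[0], 2), np.nan)
        self.flags_ = np.zeros(X.shape[0], dtype=object)
        lo = [self.BOUNDS[0][0], self.BOUNDS[1][0]]
        hi = [self.BOUNDS[0][1], self.BOUNDS[1][1]]
        for i, y in enumerate(X):
            best, best_cost = None, np.inf
            for x0 in self.STARTS:
                try:
                    res = optimize.least_squares(
                        lambda p: self._model(p[0], p[1]) - y, x0,
                        bounds=(lo, hi), xtol=1e-10, ftol=1e-10)
                except Exception:
                    continue
                if res.cost < best_cost:
                    best, best_cost = res, res.cost
            if best is None:
                self.flags_[i] = "no_convergence"
                continue
            F, k = best.x
            if F <= self.BOUNDS[0][0] * 1.5:
                self.flags_[i] = "f_at_lower_bound"
            out[i] = F, k
        return out


def fit_mt_two_pool(mt_signal, protocol: MTProtocol,
                    consts: TissueConstants | None = None):
    """Single-voxel wrapper: returns (f_bound, k_exchange, flag)."""
    f = TwoPoolMTFitter(protocol, consts).fit()
    Fk = f.transform(np.atleast_2d(mt_signal))[0]
    return float(Fk[0]), float(Fk[1]), (f.flags_[0] or None)


# ---------------------------------------------------------------------------
# reduced Watson-NODDI


def _sphere_grid(n_theta=24, n_phi=24):
    """Gauss-Legendre x uniform-azimuth quadrature on the unit sphere."""
    x, wx = np.polynomial.legendre.leggauss(n_theta)  # cos(theta) in (-1, 1)
    phi = (np.arange(n_phi) + 0.5) * 2 * np.pi / n_phi
    ct = np.repeat(x, n_phi)
    st = np.sqrt(1 - ct ** 2)
    ph = np.tile(phi, n_theta)
    U = np.column_stack([st * np.cos(ph), st * np.sin(ph), ct])
    W = np.repeat(wx, n_phi) * (2 * np.pi / n_phi)
    return U, W


#: fixed 24-point log grid for the Watson concentration
KAPPA_GRID = np.logspace(np.log10(0.25), np.log10(64.0), 24)


def orientation_dispersion(kappa) -> np.ndarray:
    """OD = (2/pi) arctan(1/kappa); 1 = isotropic, 0 = perfectly parallel."""
    return 2.0 / np.pi * np.arctan(1.0 / np.asarray(kappa, float))


class ReducedNODDIFitter(BaseEstimator, TransformerMixin):
    """Watson stick + aligned zeppelin + ball, fixed diffusivities.

    The intracellular compartment is a Watson-dispersed stick with
    d_par fixed from the tissue constants; the extracellular compartment is
    a zeppelin aligned with the fiber axis with tortuosity
    d_perp = (1 - icvf) d_par; the isotropic compartment is a ball with
    diffusivity ``d_iso``. The Watson concentration is fit on a fixed
    24-point log grid then polished by bounded 1-D searches; icvf is
    gridded and polished; iso has a closed-form conditional solution.
    The fiber axis is taken along z (through-plane), matching the
    substrate geometry; pass ``axes`` to transform to override per voxel.
    """

    def __init__(self, protocol: DiffusionProtocol | None = None,
                 consts: TissueConstants | None = None, d_iso: float = 2.0,
                 polish: bool = True):
        self.protocol = protocol
        self.consts = consts
        self.d_iso = d_iso
        self.polish = polish

    def fit(self, X=None, y=None):
        if self.protocol is None:
            raise ParameterError("a DiffusionProtocol is required")
        shells = np.unique(np.round(self.protocol.bvals[
            self.protocol.bvals > 0], 0))
        if shells.size < 2:
            raise ParameterError("reduced NODDI needs a two-shell protocol")
        self.consts_ = self.consts or TissueConstants()
        U, W = _sphere_grid()
        self.sphere_U_, self.sphere_W_ = U, W
        # Watson weights on the grid for each kappa (axis = z)
        uz2 = U[:, 2] ** 2
        wk = np.exp(KAPPA_GRID[None, :] * uz2[:, None]) * W[:, None]
        self.watson_W_ = wk / wk.sum(axis=0, keepdims=True)   # (K, n_kappa)
        self.icvf_grid_ = np.linspace(0.0, 1.0, 33)
        return self

    def _watson_weights(self, kappa):
        w = np.exp(kappa * self.sphere_U_[:, 2] ** 2) * self.sphere_W_
        return w / w.sum()

    def _signal_parts(self, x_dirs, b):
        """E (m, K) stick kernel; A_iso (m,); zeppelin pieces vs icvf."""
        d_par = self.consts_.d_par
        gu2 = (x_dirs @ self.sphere_U_.T) ** 2               # (m, K)
        E = np.exp(-(b * 1e-3 * d_par)[:, None] * gu2)       # stick kernel
        A_iso = np.exp(-b * 1e-3 * self.d_iso)
        return E, A_iso

    def _predict(self, E, A_iso, b, cz2, icvf, iso, w_kappa):
        d_par = self.consts_.d_par
        A_ic = E @ w_kappa
        d_perp = (1.0 - icvf) * d_par
        A_ec = np.exp(-b * 1e-3 * (d_perp + (d_par - d_perp) * cz2))
        base = icvf * A_ic + (1.0 - icvf) * A_ec
        return base + iso * (A_iso - base)

    def transform(self, X, axes=None) -> np.ndarray:
        """(n_voxels, n_meas) -> (n_voxels, 3) [icvf, iso, od]."""
        check_is_fitted(self)
        X = np.atleast_2d(np.asarray(X, float))
        proto = self.protocol
        b = proto.bvals
        out = np.empty((X.shape[0], 3))
        for i, x in enumerate(X):
            axis = np.array([0.0, 0.0, 1.0]) if axes is None else axes[i]
            dirs = proto.directions
            cz2 = (dirs @ axis) ** 2
            E, A_iso = self._signal_parts(dirs, b)
            out[i] = self._fit_one(x, E, A_iso, b, cz2)
        return out

    def _conditional_iso(self, x, base, A_iso):
        a = A_iso - base
        denom = float(a @ a)
        iso = 0.0 if denom == 0 else float((x - base) @ a / denom)
        return float(np.clip(iso, 0.0, 1.0))

    def _fit_one(self, x, E, A_iso, b, cz2):
        best = (np.inf, 0.5, 0.0, KAPPA_GRID[0])
        A_ic_all = E @ self.watson_W_                        # (m, n_kappa)
        d_par = self.consts_.d_par
        for j, kappa in enumerate(KAPPA_GRID):
            A_ic = A_ic_all[:, j]
            for icvf in self.icvf_grid_:
                d_perp = (1.0 - icvf) * d_par
                A_ec = np.exp(-b * 1e-3 * (d_perp + (d_par - d_perp) * cz2))
                base = icvf * A_ic + (1.0 - icvf) * A_ec
                iso = self._conditional_iso(x, base, A_iso)
                r = base + iso * (A_iso - base) - x
                sse = float(r @ r)
                if sse < best[0]:
                    best = (sse, icvf, iso, kappa)
        _, icvf, iso, kappa = best
        if self.polish:
            icvf, iso, kappa = self._polish(x, E, A_iso, b, cz2,
                                            icvf, iso, kappa)
        return icvf, iso, orientation_dispersion(kappa)

    def _polish(self, x, E, A_iso, b, cz2, icvf, iso, kappa):
        def sse_k(logk):
            w = self._watson_weights(np.exp(logk))
            r = self._predict(E, A_iso, b, cz2, icvf, iso, w) - x
            return float(r @ r)

        def sse_v(v):
            w = self._watson_weights(kappa)
            base_pred = self._predict(E, A_iso, b, cz2, v, 0.0, w)
            s = self._conditional_iso(x, base_pred, A_iso)
            r = base_pred + s * (A_iso - base_pred) - x
            return float(r @ r)

        for _ in range(2):
            lk = np.log(kappa)
            res = optimize.minimize_scalar(sse_k, bounds=(lk - 0.7, lk + 0.7),
                                           method="bounded")
            kappa = float(np.exp(res.x))
            res = optimize.minimize_scalar(
                sse_v, bounds=(max(icvf - 0.06, 0.0), min(icvf + 0.06, 1.0)),
                method="bounded")
            icvf = float(res.x)
            w = self._watson_weights(kappa)
            base = self._predict(E, A_iso, b, cz2, icvf, 0.0, w)
            iso = self._conditional_iso(x, base, A_iso)
        return icvf, iso, kappa


def fit_noddi_reduced(diffusion_signal, protocol: DiffusionProtocol,
                      consts: TissueConstants | None = None, **kw):
    """Single-voxel wrapper: returns (icvf, iso, od)."""
    f = ReducedNODDIFitter(protocol, consts, **kw).fit()
    return tuple(f.transform(np.atleast_2d(diffusion_signal))[0])


# ---------------------------------------------------------------------------
# closed forms


def g_ratio_vf(mvf, avf):
    """Aggregate voxel g-ratio from volume fractions: 1/sqrt(1 + MVF/AVF)."""
    mvf = np.asarray(mvf, float)
    avf = np.asarray(avf, float)
    if np.any(mvf < 0):
        raise ParameterError("MVF must be >= 0")
    if np.any(avf <= 0):
        raise ParameterError("AVF must be > 0 (undefined ratio otherwise)")
    out = 1.0 / np.sqrt(1.0 + mvf / avf)
    return float(out) if out.ndim == 0 else out


def g_ratio_from_maps(maps: BiophysMaps,
                      consts: TissueConstants = TissueConstants()):
    """Aggregate g-ratio from fitted maps.

    MVF inverts the bound-pool conversion; AVF aggregates the NODDI
    fractions as AVF = (1 - MVF)(1 - iso) icvf.
    """
    mvf = forward_sim.bound_pool_to_mvf(maps.f_bound, consts)
    avf = (1.0 - mvf) * (1.0 - maps.iso) * maps.icvf
    return g_ratio_vf(mvf, np.clip(avf, 1e-6, None))


def min_detectable_diameter(snr_db, D0=0.35, delta=5.0, g_exp=625.5):
    """Minimum detectable axon diameter (um) for single diffusion encoding.

    d_min = (768/7 * sigma * D0 / (gamma_h^2 * delta * g_exp^2))^(1/4) with
    the proton gyromagnetic ratio and the power-decibel noise convention
    sigma = 10^(-SNR_dB / 10). Inputs: SNR in dB, D0 in um^2/ms, delta in
    ms, g_exp in mT/m.
    """
    sigma = 10.0 ** (-np.asarray(snr_db, float) / 10.0)
    D0_si = D0 * 1e-9
    delta_si = delta * 1e-3
    g_si = g_exp * 1e-3
    d4 = (768.0 / 7.0) * sigma * D0_si / (GAMMA_H ** 2 * delta_si * g_si ** 2)
    out = d4 ** 0.25 * 1e6
    return float(out) if out.ndim == 0 else out


def roi_difference_stats(values_a, values_b, roi_masks: dict) -> dict:
    """Per-ROI (mean, median, std) differences, first input minus second."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape:
        raise ParameterError("inputs must have equal shapes")
    out = {}
    for name, mask in roi_masks.items():
        m = np.asarray(mask, bool)
        if not m.any():
            raise ParameterError(f"ROI {name!r} is empty")
        va, vb = a[m], b[m]
        out[name] = {"dmean": float(va.mean() - vb.mean()),
                     "dmedian": float(np.median(va) - np.median(vb)),
                     "dstd": float(va.std(ddof=1) - vb.std(ddof=1))}
    return out


def save_maps(maps: BiophysMaps, path, grid_shape=None, affine=None):
    """Write maps as columnar text keyed by voxel_id, or NIfTI on a grid.

    With ``grid_shape`` the seven maps are reshaped to the voxel grid and
    written as a 4-D NIfTI volume (last axis = feature); otherwise a
    tab-separated table with one row per voxel.
    """
    m = maps.context_matrix()
    if grid_shape is not None:
        import nibabel as nib
        vol = m.reshape(*grid_shape, len(BiophysMaps.FIELDS))
        aff = np.eye(4) if affine is None else affine
        nib.save(nib.Nifti1Image(vol.astype(np.float32), aff), str(path))
        return
    import pandas as pd
    df = pd.DataFrame(m, columns=list(BiophysMaps.FIELDS))
    df.insert(0, "voxel_id", np.arange(m.shape[0]))
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def load_maps(path, from_nifti=False) -> BiophysMaps:
    if from_nifti:
        import nibabel as nib
        vol = np.asarray(nib.load(str(path)).dataobj, dtype=float)
        return BiophysMaps.from_matrix(vol.reshape(-1, vol.shape[-1]))
    import pandas as pd
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    df = df.sort_values("voxel_id")
    return BiophysMaps.from_matrix(df[list(BiophysMaps.FIELDS)].to_numpy())


def fit_all_maps(diffusion: np.ndarray, mt: np.ndarray,
                 dprot: DiffusionProtocol, mtprot: MTProtocol,
                 consts: TissueConstants | None = None) -> BiophysMaps:
    """Fit all seven context maps for a block of voxels.

    ``diffusion`` is (n_voxels, n_diff_meas) and ``mt`` (n_voxels,
    n_mt_meas). NaN sentinels from failed MT fits are replaced by the
    column median so downstream standardization stays finite.
    """
    dti = DTIFitter(dprot).fit()
    fa_md = dti.transform(diffusion)
    noddi = ReducedNODDIFitter(dprot, consts).fit()
    nod = noddi.transform(diffusion)
    mtf = TwoPoolMTFitter(mtprot, consts).fit()
    fk = mtf.transform(mt)
    for col in range(fk.shape[1]):
        bad = ~np.isfinite(fk[:, col])
        if bad.any():
            fk[bad, col] = np.nanmedian(fk[:, col])
    return BiophysMaps(icvf=nod[:, 0], iso=nod[:, 1], od=nod[:, 2],
                       fa=fa_md[:, 0], md=fa_md[:, 1],
                       f_bound=fk[:, 0], k_exchange=fk[:, 1])
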