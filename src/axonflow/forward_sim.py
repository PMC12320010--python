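"""Forward MRI simulator: substrate -> normalized diffusion and MT signals.

Diffusion: each axon is an impermeable infinite cylinder (axis fixed to the
through-plane z axis) with diameter equal to the axon inner diameter. The
perpendicular signal uses the Van Gelderen finite-pulse Gaussian-phase-
distribution (GPD) series; the parallel component is free 1-D Gaussian decay
with d_par. The extracellular space is an axially symmetric tensor with
d_perp = (1 - AVF) * d_par (tortuosity). Per-measurement voxel signal:

    S = AVF * sum_i (d_i^2 / sum_j d_j^2) s_i + ECF * s_e

so myelin contributes no diffusion signal and the noiseless b=0 level equals
1 - MVF (no renormalization is applied — that deficit is itself informative).

MT: the ground-truth myelin volume fraction is converted to a bound-pool
fraction F = MVF*(1 - Phi_WM) + beta*(1 - MVF) and the MT-weighted SPGR
signal is the steady-state two-pool solution under continuous-wave-power-
equivalent saturation with a super-Lorentzian bound-pool lineshape,
normalized to the no-saturation signal.

Rician noise replaces each value v by sqrt((v + n1)^2 + n2^2) with
n1, n2 ~ N(0, sigma^2), sigma = S_ref / SNR against the voxel's unattenuated
(normalization) reference level S_ref = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import integrate, special

from .exceptions import (AccuracyError, EmptySubstrateError, ParameterError)
from .protocols import GAMMA_H, DiffusionProtocol, MTProtocol
from .substrates import VoxelSubstrate, volume_fractions

#: Default SNR ladder for noisy synthetic datasets.
SNR_LADDER = (32.0, 100.0, 316.0, 1000.0, 3160.0)


@dataclass(frozen=True)
class MTPoolConstants:
    """Two-pool MT constants (ex vivo range); inputs, not hidden defaults."""

    T2_free: float = 30.0        # ms
    T2_bound: float = 11.0e-6    # s (microsecond scale)
    T1_free: float = 1100.0      # ms
    R1_bound: float = 1.0        # 1/s, conventional fixed value
    k_exchange: float = 20.0     # 1/s, fundamental exchange rate


@dataclass(frozen=True)
class TissueConstants:
    """Diffusivity and proton-pool bookkeeping constants."""

    d_par: float = 0.35          # um^2/ms, intra- and extracellular parallel
    phi_wm: float = 0.475        # water volume fraction in myelin
    beta_bp: float = 0.086       # non-myelin bound-pool volume fraction
    mt_pool: MTPoolConstants = field(default_factory=MTPoolConstants)

    def __post_init__(self):
        if not (0 < self.phi_wm < 1 and 0 < self.beta_bp < 1 and self.d_par > 0):
            raise ParameterError("tissue constants out of range")


@dataclass
class SignalVector:
    """Normalized per-voxel MRI feature vector."""

    diffusion: np.ndarray
    mt: np.ndarray
    snr: float = math.inf

    @property
    def x(self) -> np.ndarray:
        """Concatenated feature vector fed to the encoder."""
        return np.concatenate([np.atleast_1d(self.diffusion),
                               np.atleast_1d(self.mt)])


# ---------------------------------------------------------------------------
# restricted diffusion: Van Gelderen GPD cylinder

_J1P_ROOTS_CACHE: dict[int, np.ndarray] = {}


def _j1prime_roots(n: int) -> np.ndarray:
    if n not in _J1P_ROOTS_CACHE:
        _J1P_ROOTS_CACHE[n] = special.jnp_zeros(1, n)
    return _J1P_ROOTS_CACHE[n]


def _gpd_series_sum(radius_um, delta_ms, Delta_ms, D0_um2ms,
                    n_roots: int) -> np.ndarray:
    """Gradient-independent part of the GPD log-attenuation, broadcasting.

    Returns T(R, delta, Delta) such that ln E = -2 gamma^2 G_perp^2 T.
    All inputs converted to SI internally; T has units s^2 m^2 / T^2 * ...
    (whatever makes the product dimensionless).
    """
    R = np.asarray(radius_um, float) * 1e-6
    dl = np.asarray(delta_ms, float) * 1e-3
    DL = np.asarray(Delta_ms, float) * 1e-3
    D = D0_um2ms * 1e-9

    R, dl, DL = np.broadcast_arrays(R, dl, DL)
    beta = _j1prime_roots(n_roots)          # (m,)
    a2 = (beta / R[..., None]) ** 2          # (..., m), 1/m^2
    Dd = D * a2
    num = (2.0 * Dd * dl[..., None] - 2.0
           + 2.0 * np.exp(-Dd * dl[..., None])
           + 2.0 * np.exp(-Dd * DL[..., None])
           - np.exp(-Dd * (DL - dl)[..., None])
           - np.exp(-Dd * (DL + dl)[..., None]))
    den = (D ** 2) * a2 ** 3 * (beta ** 2 - 1.0)
    terms = num / den
    total = terms.sum(axis=-1)
    # convergence diagnostic on the series tail
    rel = np.abs(terms[..., -1]) / np.maximum(np.abs(total), 1e-300)
    if np.any(rel > 1e-8):
        raise AccuracyError(
            f"GPD series tail {rel.max():.2e} > 1e-8 with {n_roots} roots")
    return total


def _gpd_series_sum_adaptive(radius_um, delta_ms, Delta_ms, D0_um2ms,
                             n_roots: int, max_roots: int) -> np.ndarray:
    n = n_roots
    while True:
        try:
            return _gpd_series_sum(radius_um, delta_ms, Delta_ms, D0_um2ms, n)
        except AccuracyError:
            if n >= max_roots:
                raise AccuracyError(
                    f"GPD series not converged with {n} roots "
                    f"(largest diameter {np.max(radius_um) * 2} um)") from None
            n *= 2


def cylinder_perp_attenuation(d, G_perp, delta, Delta, D0=0.35,
                              n_roots: int = 20, max_roots: int = 160):
    """Perpendicular PGSE attenuation for an impermeable cylinder.

    Parameters: ``d`` inner diameter (um), ``G_perp`` perpendicular gradient
    amplitude (mT/m), ``delta``/``Delta`` pulse duration/separation (ms),
    ``D0`` intrinsic diffusivity (um^2/ms). Broadcasts over array inputs.
    The Bessel-root series starts at ``n_roots`` and doubles until the tail
    term contributes < 1e-8 relative, up to ``max_roots``.
    """
    if np.any(np.asarray(d) <= 0):
        raise ParameterError("d must be > 0")
    if np.any(np.asarray(delta) >= np.asarray(Delta)):
        raise ParameterError("require delta < Delta")
    R, G, dl, DL = np.broadcast_arrays(np.asarray(d, float) / 2.0, G_perp,
                                       delta, Delta)
    T = _gpd_series_sum_adaptive(R, dl, DL, D0, n_roots, max_roots)
    lnE = -2.0 * GAMMA_H ** 2 * (G * 1e-3) ** 2 * T
    return np.exp(lnE)


def _decompose(protocol: DiffusionProtocol):
    """(b_par s/mm^2, G_perp mT/m) per measurement for a z-axis cylinder."""
    nz = protocol.directions[:, 2]
    G = protocol.gradient_amplitude
    G_par = G * np.abs(nz)
    G_perp = G * np.sqrt(np.clip(1.0 - nz ** 2, 0.0, None))
    b_par = (GAMMA_H * G_par * 1e-3 * protocol.delta_si) ** 2 \
        * (protocol.Delta_si - protocol.delta_si / 3.0) * 1e-6
    return b_par, G_perp


def intra_axonal_signal(d_in, protocol: DiffusionProtocol,
                        consts: TissueConstants = TissueConstants()):
    """Signal of cylinders of diameter ``d_in`` (um) for every measurement.

    Accepts a scalar or an array of diameters; returns shape
    ``(n_axons, n_meas)`` (squeezed to ``(n_meas,)`` for scalar input).
    s_i = exp(-b_par d_par) * GPD(d, G_perp, delta, Delta, d_par).
    """
    d = np.atleast_1d(np.asarray(d_in, float))
    b_par, G_perp = _decompose(protocol)
    par = np.exp(-b_par * 1e6 * (consts.d_par * 1e-9))  # b_si [s/m^2] * D_si
    # the root series depends only on (R, delta, Delta): evaluate it once per
    # timing block and scale by G_perp^2 per measurement
    timing = np.column_stack([protocol.delta, protocol.Delta])
    uniq, inv = np.unique(timing, axis=0, return_inverse=True)
    T = np.empty((d.size, uniq.shape[0]))
    for j, (dl, DL) in enumerate(uniq):
        T[:, j] = _gpd_series_sum_adaptive(d / 2.0, dl, DL, consts.d_par,
                                           20, 160)
    lnE = -2.0 * GAMMA_H ** 2 * (G_perp * 1e-3) ** 2 * T[:, inv]
    out = par[None, :] * np.exp(lnE)
    return out[0] if np.isscalar(d_in) or np.ndim(d_in) == 0 else out


def extracellular_signal(protocol: DiffusionProtocol, avf: float,
                         consts: TissueConstants = TissueConstants()):
    """Tortuosity-tensor extracellular signal per measurement.

    Axially symmetric Gaussian tensor aligned with the cylinder axis:
    s_e = exp(-b_par d_par - b_perp (1 - AVF) d_par).
    """
    if not 0 <= avf <= 1:
        raise ParameterError("AVF must be in [0, 1]")
    b_par, G_perp = _decompose(protocol)
    b_perp = (GAMMA_H * G_perp * 1e-3 * protocol.delta_si) ** 2 \
        * (protocol.Delta_si - protocol.delta_si / 3.0) * 1e-6
    D_si = consts.d_par * 1e-9
    return np.exp(-(b_par + (1.0 - avf) * b_perp) * 1e6 * D_si)


def mix_voxel_signal(substrate: VoxelSubstrate, protocol: DiffusionProtocol,
                     consts: TissueConstants = TissueConstants()) -> np.ndarray:
    """Noiseless normalized diffusion signal of one voxel, per measurement.

    Intra-axonal signals are weighted by d_i^2 / sum_j d_j^2 (cross-sectional
    area weighting of the printed mixing rule); the myelin compartment is
    invisible, so the b=0 value equals 1 - MVF.
    """
    if substrate.n_axons == 0:
        raise EmptySubstrateError("cannot simulate an empty substrate")
    avf, mvf, ecf = volume_fractions(substrate)
    s_i = intra_axonal_signal(substrate.d_in, protocol, consts)
    w = substrate.d_in ** 2
    w = w / w.sum()
    s_e = extracellular_signal(protocol, avf, consts)
    return avf * (w @ s_i) + ecf * s_e


# ---------------------------------------------------------------------------
# magnetization transfer


def mvf_to_bound_pool(mvf, consts: TissueConstants = TissueConstants()):
    """Bound-pool fraction from myelin volume fraction.

    Proton-volume bookkeeping: the myelin macromolecular fraction
    MVF*(1 - Phi_WM) plus the non-myelin bound pool beta*(1 - MVF).
    Strictly increasing in MVF; F(0) = beta, F(1) = 1 - Phi_WM.
    """
    mvf = np.asarray(mvf, float)
    if np.any(mvf < 0) or np.any(mvf > 1):
        raise ParameterError("MVF must be in [0, 1]")
    out = mvf * (1.0 - consts.phi_wm) + consts.beta_bp * (1.0 - mvf)
    return float(out) if out.ndim == 0 else out


def bound_pool_to_mvf(F, consts: TissueConstants = TissueConstants()):
    """Closed-form inverse of :func:`mvf_to_bound_pool`."""
    F = np.asarray(F, float)
    out = (F - consts.beta_bp) / (1.0 - consts.phi_wm - consts.beta_bp)
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


_SL_CACHE: dict[tuple, float] = {}


def super_lorentzian(offset_hz: float, T2b_s: float) -> float:
    """Super-Lorentzian absorption lineshape value G(offset) in seconds.

    G = sqrt(2/pi) T2b int_0^1 du / |3u^2 - 1| exp(-2 (2 pi f T2b / (3u^2-1))^2).
    The integrand vanishes at the magic angle for any nonzero offset; offsets
    below 100 Hz are clamped to 100 Hz (standard on-resonance cutoff, logged
    by the caller).
    """
    f = max(float(offset_hz), 100.0)
    key = (round(f, 6), T2b_s)
    if key not in _SL_CACHE:
        w = 2.0 * np.pi * f

        def integrand(u):
            s = np.abs(3.0 * u * u - 1.0)
            s = np.maximum(s, 1e-12)
            return np.sqrt(2.0 / np.pi) * T2b_s / s * np.exp(
                -2.0 * (w * T2b_s / s) ** 2)

        val, _ = integrate.quad(integrand, 0.0, 1.0,
                                points=[1.0 / np.sqrt(3.0)], limit=200)
        _SL_CACHE[key] = val
    return _SL_CACHE[key]


def mt_spgr_signal(F, protocol: MTProtocol,
                   consts: TissueConstants = TissueConstants()) -> np.ndarray:
    """Normalized steady-state two-pool MT-weighted signal per measurement.

    Continuous-wave power-equivalent saturation: the bound pool saturates at
    Rb = pi omega1^2 G_SL(offset); the free pool sees direct (Lorentzian)
    saturation Rf = omega1^2 T2f / (1 + (2 pi f T2f)^2). The coupled
    longitudinal steady state is solved in closed form and divided by the
    no-saturation steady state, so the output is 1 at vanishing saturation.
    Accepts scalar or array F; returns ``(n_meas,)`` or ``(n_F, n_meas)``.
    """
    Farr = np.atleast_1d(np.asarray(F, float))
    if np.any(Farr <= 0) or np.any(Farr >= 1):
        raise ParameterError("F must be in (0, 1)")
    mp = consts.mt_pool
    R1f = 1.0 / (mp.T1_free * 1e-3)
    R1b = mp.R1_bound
    T2f = mp.T2_free * 1e-3
    k = mp.k_exchange

    w1 = protocol.omega1_cwpe                       # (m,)
    f_off = protocol.offsets
    G_sl = np.array([super_lorentzian(f, mp.T2_bound) for f in f_off])
    Rb = np.pi * w1 ** 2 * G_sl                     # (m,)
    Rf = w1 ** 2 * T2f / (1.0 + (2.0 * np.pi * f_off * T2f) ** 2)

    M0f = (1.0 - Farr)[:, None]
    M0b = Farr[:, None]
    kf = (k * Farr)[:, None]
    kb = (k * (1.0 - Farr))[:, None]
    num = R1f * M0f * (R1b + kb + Rb[None, :]) + kb * R1b * M0b
    den = (R1f + kf + Rf[None, :]) * (R1b + kb + Rb[None, :]) - kf * kb
    S = num / den / M0f
    return S[0] if np.ndim(F) == 0 else S


# ---------------------------------------------------------------------------
# noise and dataset assembly


def add_rician_noise(signal: SignalVector, snr: float,
                     seed_or_rng=None, s_ref: float = 1.0) -> SignalVector:
    """Rician-corrupt a signal vector at the given SNR (inf = identity).

    sigma = s_ref / snr with s_ref the voxel's unattenuated reference level
    on the normalized scale.
    """
    if not snr > 0:
        raise ParameterError("snr must be > 0 (use inf for noiseless)")
    if math.isinf(snr):
        return replace(signal, snr=math.inf)
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    sigma = s_ref / snr

    def rice(v):
        v = np.asarray(v, float)
        n1 = rng.normal(0.0, sigma, v.shape)
        n2 = rng.normal(0.0, sigma, v.shape)
        return np.sqrt((v + n1) ** 2 + n2 ** 2)

    return SignalVector(rice(signal.diffusion), rice(signal.mt), snr=snr)


def simulate_voxel(substrate: VoxelSubstrate, dprot: DiffusionProtocol,
                   mtprot: MTProtocol,
                   consts: TissueConstants = TissueConstants()) -> SignalVector:
    """Noiseless diffusion + MT signal vector for one substrate.

    MT uses the frozen MVF when the substrate was diameter-rescaled.
    """
    diff = mix_voxel_signal(substrate, dprot, consts)
    mvf = substrate.mvf_frozen
    if mvf is None:
        mvf = volume_fractions(substrate)[1]
    F = mvf_to_bound_pool(mvf, consts)
    F = float(np.clip(F, 1e-4, 1.0 - 1e-4))
    mt = mt_spgr_signal(F, mtprot, consts)
    return SignalVector(diff, mt, snr=math.inf)


def simulate_dataset(substrates: list[VoxelSubstrate],
                     dprot: DiffusionProtocol, mtprot: MTProtocol,
                     snrs=(math.inf,), seed: int = 0,
                     consts: TissueConstants = TissueConstants()):
    """Simulate every substrate at every SNR of the ladder.

    Returns ``(signals, voxel_index)``: ``signals`` is a list of
    SignalVector of length ``len(substrates) * len(snrs)`` and
    ``voxel_index[i]`` maps each signal back to its substrate. Bit
    reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    clean = [simulate_voxel(s, dprot, mtprot, consts) for s in substrates]
    signals, voxel_index = [], []
    for snr in snrs:
        for i, sv in enumerate(clean):
            signals.append(add_rician_noise(sv, snr, rng))
            voxel_index.append(i)
    return signals, np.asarray(voxel_index)
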