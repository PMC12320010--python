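"""Shared fixtures and independent numerical oracles.

The oracles here deliberately avoid the package's analytic code paths:
restricted diffusion is checked against a reflecting random-walk phase
simulation, and the two-pool MT closed form against direct numerical
integration of the Bloch-McConnell longitudinal equations.
"""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from axonflow import biophys_maps, forward_sim, protocols, substrates, train
from axonflow.cnfm import protocol_fingerprint

GAMMA = 2.675e8  # rad/s/T, proton


# ---------------------------------------------------------------------------
# Monte-Carlo random-walk oracle for restricted diffusion in a cylinder


def mc_cylinder_attenuation(d_um, G_mTm, delta_ms, Delta_ms, D0=0.35,
                            n_walkers=20000, dt_ms=0.005, seed=1234):
    """PGSE attenuation from a 2-D reflecting random walk inside a disk.

    Walkers diffuse in the plane perpendicular to the cylinder axis with
    reflecting boundary; each accumulates phase gamma * G * x * dt during
    the two rectangular gradient lobes (opposite signs); the attenuation is
    the ensemble mean of cos(phase).
    """
    rng = np.random.default_rng(seed)
    R = d_um / 2.0
    step = np.sqrt(2.0 * D0 * dt_ms)  # per-axis step std, um
    # uniform initial positions in the disk
    r = R * np.sqrt(rng.random(n_walkers))
    th = 2 * np.pi * rng.random(n_walkers)
    pos = np.column_stack([r * np.cos(th), r * np.sin(th)])
    phase = np.zeros(n_walkers)
    n_steps = int(round((Delta_ms + delta_ms) / dt_ms))
    G_si = G_mTm * 1e-3
    dt_s = dt_ms * 1e-3
    for i in range(n_steps):
        pos += rng.normal(0.0, step, pos.shape)
        rad = np.sqrt((pos ** 2).sum(axis=1))
        out = rad > R
        if out.any():
            pos[out] *= ((2 * R - rad[out]) / rad[out])[:, None]
        t = (i + 0.5) * dt_ms
        if t < delta_ms:
            phase += GAMMA * G_si * pos[:, 0] * 1e-6 * dt_s
        elif Delta_ms <= t < Delta_ms + delta_ms:
            phase -= GAMMA * G_si * pos[:, 0] * 1e-6 * dt_s
    return float(np.mean(np.cos(phase)))


#: (preset, amplitude tier) -> (G mT/m, delta ms, Delta ms)
MC_CONFIGS = {("mouse", "lo"): (312.7, 5.0, 18.0),
              ("mouse", "hi"): (625.5, 5.0, 18.0),
              ("cord", "lo"): (300.0, 8.0, 25.0),
              ("cord", "hi"): (600.0, 8.0, 25.0)}
MC_DIAMETERS = (0.3, 1.0, 2.0, 5.0)


@pytest.fixture(scope="session")
def mc_oracle():
    """MC attenuations for 4 diameters x both presets x two amplitudes."""
    out = {}
    for key, (G, dl, DL) in MC_CONFIGS.items():
        for d in MC_DIAMETERS:
            out[key + (d,)] = mc_cylinder_attenuation(d, G, dl, DL)
    return out


# ---------------------------------------------------------------------------
# Bloch-McConnell ODE oracle for the two-pool MT steady state


def bloch_mcconnell_mt(F, omega1, offset_hz, consts=None):
    """Normalized free-pool steady state by direct ODE integration."""
    c = consts or forward_sim.TissueConstants()
    mp = c.mt_pool
    R1f = 1.0 / (mp.T1_free * 1e-3)
    R1b = mp.R1_bound
    T2f = mp.T2_free * 1e-3
    k = mp.k_exchange
    kf, kb = k * F, k * (1.0 - F)
    M0f, M0b = 1.0 - F, F
    Rb = np.pi * omega1 ** 2 * forward_sim.super_lorentzian(offset_hz,
                                                           mp.T2_bound)
    Rf = omega1 ** 2 * T2f / (1.0 + (2 * np.pi * offset_hz * T2f) ** 2)

    def rhs(_, M):
        Mf, Mb = M
        return [R1f * (M0f - Mf) - kf * Mf + kb * Mb - Rf * Mf,
                R1b * (M0b - Mb) - kb * Mb + kf * Mf - Rb * Mb]

    sol = solve_ivp(rhs, (0.0, 60.0), [M0f, M0b], rtol=1e-10, atol=1e-12)
    return float(sol.y[0, -1] / M0f)


# ---------------------------------------------------------------------------
# protocols and a small trained model


@pytest.fixture(scope="session")
def mouse_protocols():
    return (protocols.builtin_presets("mouse_pretrain_diffusion"),
            protocols.builtin_presets("mouse_pretrain_mt"))


@pytest.fixture(scope="session")
def small_dataset(mouse_protocols):
    """~180 noisy synthetic voxels with fitted context maps."""
    dprot, mtprot = mouse_protocols
    params = substrates.SubstrateParams(seed=21)
    base = substrates.filter_population(
        substrates.sample_population(params, 60, seed=21), 400)
    sigs, vidx = forward_sim.simulate_dataset(
        base, dprot, mtprot, snrs=(100.0, 316.0, 1000.0), seed=22)
    ds = train.assemble_dataset(base, sigs, vidx, dprot.n_measurements,
                                mtprot.n_measurements)
    nd = dprot.n_measurements
    maps = biophys_maps.fit_all_maps(ds.signals[:, :nd], ds.signals[:, nd:],
                                     dprot, mtprot)
    ds.maps = maps.context_matrix()
    return ds


@pytest.fixture(scope="session")
def pretrained_small(small_dataset, mouse_protocols):
    """A modest pretrained model plus its training history and split."""
    dprot, mtprot = mouse_protocols
    cfg = train.TrainConfig(epochs=24, monitor_every=3, monitor_voxels=30,
                            batch_voxels=64, patience=24)
    return train.pretrain(small_dataset, cfg, seed=7,
                          fingerprint=protocol_fingerprint(dprot, mtprot))


@pytest.fixture(scope="session")
def mouse_transfer_dataset():
    """Small labelled mouse-like dataset for transfer/multitask tests."""
    from axonflow.cli import ExperimentConfig, make_mouse_dataset
    return make_mouse_dataset(ExperimentConfig(), seed=31)
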