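"""Acquisition tables: diffusion (PGSE) and magnetization-transfer protocols.

Units at the interface follow the printed conventions of preclinical
protocols — gradient amplitude in mT/m, timings in ms, offsets in Hz,
equivalent MT flip angles in degrees. Conversion to SI happens once, inside
the accessor properties, so downstream physics code never carries unit
factors.

Built-in presets cover the mouse pretraining protocol (2 shells x 36
directions + 4 b=0, delta/Delta = 5/18 ms, |G| in {312.7, 625.5} mT/m; MT
with equivalent angles 1000/4000 deg over 7 offsets) and the spinal-cord
reference protocol (49 amplitudes 85.7-600 mT/m + 1 G=0 per timing block,
single direction, four delta/Delta blocks; MT with angles 142/500 deg over
nine offsets 400-18000 Hz).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError, PresetLookupError, ProtocolFormatError

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_H = 2.675e8


def b_value(G_mTm, delta_ms, Delta_ms):
    """PGSE b-value in s/mm^2 for rectangular gradients.

    b = (gamma G delta)^2 (Delta - delta/3), evaluated in SI and returned
    in the conventional s/mm^2.
    """
    G = np.asarray(G_mTm, dtype=float) * 1e-3          # T/m
    d = np.asarray(delta_ms, dtype=float) * 1e-3       # s
    D = np.asarray(Delta_ms, dtype=float) * 1e-3       # s
    b_si = (GAMMA_H * G * d) ** 2 * (D - d / 3.0)      # s/m^2
    return b_si * 1e-6


@dataclass(frozen=True)
class DiffusionProtocol:
    """Per-measurement PGSE table.

    ``directions`` are unit 3-vectors (arbitrary for G = 0 rows);
    b=0 rows are stored explicitly as zero-amplitude measurements.
    """

    directions: np.ndarray        # (n, 3)
    gradient_amplitude: np.ndarray  # mT/m, (n,)
    delta: np.ndarray             # ms, (n,)
    Delta: np.ndarray             # ms, (n,)
    TE: float | None = None      # ms, metadata
    TR: float | None = None      # ms, metadata
    name: str = ""

    def __post_init__(self):
        dirs = np.atleast_2d(np.asarray(self.directions, dtype=float))
        amp = np.atleast_1d(np.asarray(self.gradient_amplitude, dtype=float))
        d = np.broadcast_to(np.asarray(self.delta, dtype=float), amp.shape).copy()
        D = np.broadcast_to(np.asarray(self.Delta, dtype=float), amp.shape).copy()
        object.__setattr__(self, "directions", dirs)
        object.__setattr__(self, "gradient_amplitude", amp)
        object.__setattr__(self, "delta", d)
        object.__setattr__(self, "Delta", D)
        if dirs.shape != (amp.size, 3):
            raise ProtocolFormatError("directions must be (n, 3) matching amplitudes")
        if np.any(amp < 0):
            raise ParameterError("gradient amplitudes must be >= 0")
        if np.any(d >= D):
            raise ParameterError("require delta < Delta for every measurement")
        norms = np.linalg.norm(dirs[amp > 0], axis=1)
        if norms.size and np.any(np.abs(norms - 1.0) > 1e-6):
            raise ProtocolFormatError("directions must be unit-norm within 1e-6")

    @property
    def n_measurements(self) -> int:
        return int(self.gradient_amplitude.size)

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.gradient_amplitude == 0))

    @property
    def bvals(self) -> np.ndarray:
        """b-values in s/mm^2."""
        return b_value(self.gradient_amplitude, self.delta, self.Delta)

    # SI accessors used by the physics code
    @property
    def G_si(self) -> np.ndarray:
        return self.gradient_amplitude * 1e-3  # T/m

    @property
    def delta_si(self) -> np.ndarray:
        return self.delta * 1e-3  # s

    @property
    def Delta_si(self) -> np.ndarray:
        return self.Delta * 1e-3  # s


@dataclass(frozen=True)
class MTProtocol:
    """MT-weighted SPGR table: one measurement per (angle, offset) pair."""

    flip_angles_equiv: np.ndarray  # degrees, (n,)
    offsets: np.ndarray            # Hz, (n,)
    TR: float = 421.0              # ms
    TE: float = 3.3                # ms
    #: duration of the equivalent rectangular MT pulse used for the
    #: continuous-wave power-equivalent amplitude (ms)
    pulse_duration: float = 10.0
    name: str = ""

    def __post_init__(self):
        ang = np.atleast_1d(np.asarray(self.flip_angles_equiv, dtype=float))
        off = np.atleast_1d(np.asarray(self.offsets, dtype=float))
        object.__setattr__(self, "flip_angles_equiv", ang)
        object.__setattr__(self, "offsets", off)
        if ang.shape != off.shape:
            raise ProtocolFormatError("angles and offsets must pair one-to-one")
        if np.any(ang <= 0) or np.any(off <= 0):
            raise ParameterError("angles and offsets must be > 0")

    @property
    def n_measurements(self) -> int:
        return int(self.offsets.size)

    @property
    def omega1_cwpe(self) -> np.ndarray:
        """CW-power-equivalent B1 amplitude, rad/s, per measurement.

        The equivalent flip angle theta of a rectangular pulse of duration
        tau gives int omega1^2 dt = (theta/tau)^2 tau; averaging the power
        over TR yields omega1_rms = theta / sqrt(tau * TR).
        """
        theta = np.deg2rad(self.flip_angles_equiv)
        tau = self.pulse_duration * 1e-3
        TR = self.TR * 1e-3
        return theta / np.sqrt(tau * TR)

    @classmethod
    def from_grid(cls, angles_deg, offsets_hz, **kw) -> "MTProtocol":
        A, O = np.meshgrid(np.asarray(angles_deg, float),
                           np.asarray(offsets_hz, float), indexing="ij")
        return cls(A.ravel(), O.ravel(), **kw)


# ---------------------------------------------------------------------------
# FSL-style I/O


def _fib_hemisphere(n: int) -> np.ndarray:
    """Deterministic, well-spread unit directions on the upper hemisphere."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + 5 ** 0.5) * i
    z = i / n  # (0, 1): hemisphere
    r = np.sqrt(1.0 - z ** 2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def save_diffusion_protocol(proto: DiffusionProtocol, bval_path, bvec_path,
                            timing_path) -> None:
    """FSL bval/bvec plus a JSON sidecar carrying delta/Delta/amplitudes."""
    np.savetxt(bval_path, proto.bvals[None, :], fmt="%.8g")
    np.savetxt(bvec_path, proto.directions.T, fmt="%.17g")
    with open(timing_path, "w") as f:
        json.dump({"delta_ms": proto.delta.tolist(),
                   "Delta_ms": proto.Delta.tolist(),
                   "gradient_amplitude_mTm": proto.gradient_amplitude.tolist(),
                   "TE_ms": proto.TE, "TR_ms": proto.TR,
                   "name": proto.name}, f, indent=1)


def load_diffusion_protocol(bval_path, bvec_path, timing_config) -> DiffusionProtocol:
    """Read an FSL-dialect bval/bvec pair plus a timing config.

    ``timing_config`` is a dict or a path to the JSON sidecar written by
    :func:`save_diffusion_protocol`; it supplies delta, Delta and the
    gradient amplitudes. The stored b-values are cross-checked against
    b = (gamma G delta)^2 (Delta - delta/3); mismatch beyond 1% logs a
    warning (the timing table wins).
    """
    bvals = np.loadtxt(bval_path, ndmin=2).ravel()
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] != 3:
        raise ProtocolFormatError("bvec must be 3 rows x N columns")
    if bvecs.shape[1] != bvals.size:
        raise ProtocolFormatError(
            f"bval has {bvals.size} entries but bvec has {bvecs.shape[1]} columns")
    if isinstance(timing_config, (str, bytes)) or hasattr(timing_config, "read_text"):
        with open(timing_config) as f:
            timing_config = json.load(f)
    proto = DiffusionProtocol(
        directions=bvecs.T,
        gradient_amplitude=np.asarray(timing_config["gradient_amplitude_mTm"]),
        delta=np.asarray(timing_config["delta_ms"]),
        Delta=np.asarray(timing_config["Delta_ms"]),
        TE=timing_config.get("TE_ms"), TR=timing_config.get("TR_ms"),
        name=timing_config.get("name", ""))
    pred = proto.bvals
    nz = pred > 0
    if np.any(nz):
        rel = np.abs(pred[nz] - bvals[nz]) / np.maximum(pred[nz], 1e-12)
        if np.any(rel > 0.01):
            warnings.warn(
                "stored b-values differ from (gamma G delta)^2 (Delta - delta/3) "
                f"by up to {100 * rel.max():.1f}%; using the timing table",
                stacklevel=2)
    return proto


def save_mt_protocol(proto: MTProtocol, path) -> None:
    with open(path, "w") as f:
        json.dump({"flip_angles_equiv_deg": proto.flip_angles_equiv.tolist(),
                   "offsets_hz": proto.offsets.tolist(), "TR_ms": proto.TR,
                   "TE_ms": proto.TE, "pulse_duration_ms": proto.pulse_duration,
                   "name": proto.name}, f, indent=1)


def load_mt_protocol(path) -> MTProtocol:
    with open(path) as f:
        d = json.load(f)
    return MTProtocol(np.asarray(d["flip_angles_equiv_deg"]),
                      np.asarray(d["offsets_hz"]), TR=d["TR_ms"], TE=d["TE_ms"],
                      pulse_duration=d.get("pulse_duration_ms", 10.0),
                      name=d.get("name", ""))


# ---------------------------------------------------------------------------
# presets


def _mouse_pretrain_diffusion() -> DiffusionProtocol:
    dirs36 = _fib_hemisphere(36)
    directions = np.vstack([np.tile([0.0, 0.0, 1.0], (4, 1)),
                            dirs36, dirs36])
    amps = np.concatenate([np.zeros(4), np.full(36, 312.7), np.full(36, 625.5)])
    return DiffusionProtocol(directions, amps, delta=5.0, Delta=18.0,
                             TE=56.6, TR=1050.0, name="mouse_pretrain_diffusion")


def _cord_reference_diffusion() -> DiffusionProtocol:
    blocks = [(7.0, 3.0), (25.0, 8.0), (35.0, 8.0), (40.0, 8.0)]  # (Delta, delta)
    amps, deltas, Deltas = [], [], []
    for Delta, delta in blocks:
        amps.append(np.concatenate([[0.0], np.linspace(85.7, 600.0, 49)]))
        deltas.append(np.full(50, delta))
        Deltas.append(np.full(50, Delta))
    amps = np.concatenate(amps)
    directions = np.tile([1.0, 0.0, 0.0], (amps.size, 1))
    return DiffusionProtocol(directions, amps,
                             delta=np.concatenate(deltas),
                             Delta=np.concatenate(Deltas),
                             name="cord_reference_diffusion")


_MOUSE_MT_OFFSETS = [1000.0, 2000.0, 4000.0, 6000.0, 10000.0, 22000.0, 30000.0]
_CORD_MT_OFFSETS = [400.0, 800.0, 1000.0, 2200.0, 3000.0, 4000.0, 7000.0,
                    16000.0, 18000.0]

_PRESETS = {
    "mouse_pretrain_diffusion": _mouse_pretrain_diffusion,
    "cord_reference_diffusion": _cord_reference_diffusion,
    "mouse_pretrain_mt": lambda: MTProtocol.from_grid(
        [1000.0, 4000.0], _MOUSE_MT_OFFSETS, TR=421.0, TE=3.3,
        name="mouse_pretrain_mt"),
    "cord_reference_mt": lambda: MTProtocol.from_grid(
        [142.0, 500.0], _CORD_MT_OFFSETS, TR=421.0, TE=3.3,
        name="cord_reference_mt"),
}


def builtin_presets(name: str):
    """Return a built-in protocol by name; raises on unknown names."""
    try:
        return _PRESETS[name]()
    except KeyError:
        raise PresetLookupError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}") from None
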