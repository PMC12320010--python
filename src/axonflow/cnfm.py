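"""Conditional normalizing-flow density model (cNFM).

Architecture: the voxel's concatenated diffusion + MT feature vector passes
through an MLP encoder (64/32/16 units, PReLU, batch norm before layers 2
and 3) producing a 16-dimensional embedding; seven fitted biophysical map
values are concatenated to form the 23-dimensional context vector. Two
masked autoregressive flow blocks, conditioned on the context through their
conditioner inputs, map a bivariate standard normal to the joint law of
(axon diameter, g-ratio).

Support handling: diameters are modelled as log(d) and g-ratios as
logit(g), standardized by training statistics, so the flow lives on R^2;
reported densities carry the corresponding Jacobian corrections. The
working rectangle for quadrature is d in (0, d_max] with d_max three times
the 99th percentile of the training diameters, and g in (0, 1).

During transfer learning two classification heads (cortical region and
mouse group) attach to the context vector for multi-task training.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np

from ._autodiff import (BatchNorm, Dropout, Linear, Module, PReLU,
                        Tensor, softmax_np)
from .exceptions import NumericalStabilityError, ParameterError, ProtocolFormatError
from .substrates import GROUPS, REGIONS

_LOG2PI = float(np.log(2.0 * np.pi))
_ALPHA_CLAMP = 4.0  # soft bound on log-scales keeps the transform invertible


@dataclass(frozen=True)
class EncoderSpec:
    layer_widths: tuple = (64, 32, 16)
    dropout_rate: float = 0.0

    def __post_init__(self):
        if self.layer_widths[-1] != 16:
            raise ParameterError("encoder output width must be 16")
        if not 0 <= self.dropout_rate < 1:
            raise ParameterError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class FlowSpec:
    n_blocks: int = 2
    hidden_units: int = 64


#: recognised ablation switches
ABLATIONS = ("diffusion_only", "mt_only", "no_maps", "no_multitask",
             "no_pretrain")

#: order of the 7 map features in the context
MAP_FIELDS = ("icvf", "iso", "od", "fa", "md", "f_bound", "k_exchange")
_DIFFUSION_MAPS = (0, 1, 2, 3, 4)   # icvf, iso, od, fa, md
_MT_MAPS = (5, 6)                   # f_bound, k_exchange


def protocol_fingerprint(dprot, mtprot) -> str:
    h = hashlib.sha256()
    for arr in (dprot.directions, dprot.gradient_amplitude, dprot.delta,
                dprot.Delta, mtprot.flip_angles_equiv, mtprot.offsets):
        h.update(np.ascontiguousarray(arr, dtype=np.float64).tobytes())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# masked autoregressive block


def _made_masks(n_ctx: int, hidden: int, rng) -> list[np.ndarray]:
    """Masks for a 2-in/4-out MADE whose context inputs carry degree 0."""
    deg_in = np.array([1, 2] + [0] * n_ctx)
    half = hidden // 2
    deg_h = np.array([0] * half + [1] * (hidden - half))
    deg_out = np.array([1, 2, 1, 2])  # mu1, mu2, alpha1, alpha2
    m1 = (deg_h[None, :] >= deg_in[:, None]).astype(float)
    m2 = (deg_h[None, :] >= deg_h[:, None]).astype(float)
    m3 = (deg_out[None, :] > deg_h[:, None]).astype(float)
    return [m1, m2, m3]


class MADEBlock(Module):
    """One masked-autoregressive transform u -> z with context conditioning."""

    def __init__(self, n_ctx: int, hidden: int, rng):
        m1, m2, m3 = _made_masks(n_ctx, hidden, rng)
        self.l1 = Linear(2 + n_ctx, hidden, rng, mask=m1)
        self.l2 = Linear(hidden, hidden, rng, mask=m2)
        self.l3 = Linear(hidden, 4, rng, mask=m3)
        # start near the identity transform (mu = 0, alpha = 0)
        self.l3.W.data *= 0.01
        self.n_ctx = n_ctx

    def _net(self, uc: Tensor) -> Tensor:
        return self.l3(self.l2(self.l1(uc).relu()).relu())

    def _net_np(self, uc: np.ndarray) -> np.ndarray:
        r = lambda x: np.maximum(x, 0.0)
        return self.l3.forward_np(r(self.l2.forward_np(r(self.l1.forward_np(uc)))))

    @staticmethod
    def _split(out):
        mu, raw = out[:, 0:2], out[:, 2:4]
        if isinstance(out, Tensor):
            alpha = (raw * (1.0 / _ALPHA_CLAMP)).tanh() * _ALPHA_CLAMP
        else:
            alpha = np.tanh(raw / _ALPHA_CLAMP) * _ALPHA_CLAMP
        return mu, alpha

    def forward(self, u: Tensor, ctx: Tensor):
        """(z, sum_log_scale) on the graph path; logdet = -sum_log_scale."""
        mu, alpha = self._split(self._net(Tensor.concat([u, ctx], axis=1)))
        z = (u - mu) * (-alpha).exp()
        return z, alpha.sum(axis=1)

    def forward_np(self, u: np.ndarray, ctx: np.ndarray):
        mu, alpha = self._split(self._net_np(np.concatenate([u, ctx], axis=1)))
        return (u - mu) * np.exp(-alpha), alpha.sum(axis=1)

    def invert_np(self, z: np.ndarray, ctx: np.ndarray) -> np.ndarray:
        u = np.zeros_like(z)
        for i in range(2):  # autoregressive dims resolved in order
            mu, alpha = self._split(
                self._net_np(np.concatenate([u, ctx], axis=1)))
            u[:, i] = mu[:, i] + z[:, i] * np.exp(alpha[:, i])
        return u


class ConditionalFlow(Module):
    """Stack of MADE blocks with a dimension flip between blocks."""

    def __init__(self, n_ctx: int, spec: FlowSpec, rng):
        self.blocks = [MADEBlock(n_ctx, spec.hidden_units, rng)
                       for _ in range(spec.n_blocks)]
        self.spec = spec

    def log_prob(self, u: Tensor, ctx: Tensor) -> Tensor:
        total = Tensor(np.zeros(u.shape[0]))
        z = u
        for i, blk in enumerate(self.blocks):
            if i > 0:
                z = z[:, ::-1]
            z, sum_alpha = blk.forward(z, ctx)
            total = total + sum_alpha
        base = (-0.5) * (z * z).sum(axis=1) - _LOG2PI
        return base - total

    def log_prob_np(self, u: np.ndarray, ctx: np.ndarray) -> np.ndarray:
        total = np.zeros(u.shape[0])
        z = u
        for i, blk in enumerate(self.blocks):
            if i > 0:
                z = z[:, ::-1]
            z, sum_alpha = blk.forward_np(z, ctx)
            total = total + sum_alpha
        return -0.5 * (z ** 2).sum(axis=1) - _LOG2PI - total

    def forward_np(self, u: np.ndarray, ctx: np.ndarray) -> np.ndarray:
        z = u
        for i, blk in enumerate(self.blocks):
            if i > 0:
                z = z[:, ::-1]
            z, _ = blk.forward_np(z, ctx)
        return z

    def invert_np(self, z: np.ndarray, ctx: np.ndarray) -> np.ndarray:
        u = z
        for i, blk in enumerate(reversed(self.blocks)):
            u = blk.invert_np(u, ctx)
            if i < len(self.blocks) - 1:
                u = u[:, ::-1]
        return u


# ---------------------------------------------------------------------------
# encoder and heads


class Encoder(Module):
    """MLP signal encoder: widths 64/32/16, PReLU, BN before layers 2 and 3."""

    def __init__(self, n_in: int, spec: EncoderSpec, rng):
        w1, w2, w3 = spec.layer_widths
        self.l1 = Linear(n_in, w1, rng)
        self.a1 = PReLU()
        self.bn2 = BatchNorm(w1)
        self.l2 = Linear(w1, w2, rng)
        self.a2 = PReLU()
        self.bn3 = BatchNorm(w2)
        self.l3 = Linear(w2, w3, rng)
        self.a3 = PReLU()
        self.drop = Dropout(spec.dropout_rate)

    def __call__(self, x: Tensor, training: bool, rng=None) -> Tensor:
        h = self.drop(self.a1(self.l1(x)), training, rng)
        h = self.drop(self.a2(self.l2(self.bn2(h, training))), training, rng)
        return self.a3(self.l3(self.bn3(h, training)))

    def forward_np(self, x: np.ndarray) -> np.ndarray:
        h = self.a1.forward_np(self.l1.forward_np(x))
        h = self.a2.forward_np(self.l2.forward_np(self.bn2.forward_np(h)))
        return self.a3.forward_np(self.l3.forward_np(self.bn3.forward_np(h)))


class ClassifierHead(Module):
    def __init__(self, n_ctx: int, n_classes: int, rng, hidden: int = 16):
        self.l1 = Linear(n_ctx, hidden, rng)
        self.a1 = PReLU()
        self.l2 = Linear(hidden, n_classes, rng)

    def __call__(self, ctx: Tensor) -> Tensor:
        return self.l2(self.a1(self.l1(ctx)))

    def forward_np(self, ctx: np.ndarray) -> np.ndarray:
        return self.l2.forward_np(self.a1.forward_np(self.l1.forward_np(ctx)))


# ---------------------------------------------------------------------------
# the full model


@dataclass
class Standardization:
    """Training-set statistics stored with the model."""

    x_mean: np.ndarray = None
    x_std: np.ndarray = None
    maps_mean: np.ndarray = None
    maps_std: np.ndarray = None
    u_mean: np.ndarray = None   # (mean log d, mean logit g)
    u_std: np.ndarray = None
    d_max: float = 10.0         # working-rectangle upper edge, um

    def to_dict(self):
        return {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.__dict__.items()}

    @classmethod
    def from_dict(cls, d):
        out = cls()
        for k, v in d.items():
            setattr(out, k, np.asarray(v) if isinstance(v, list) else v)
        return out


class CNFM(Module):
    """Encoder + conditional MAF + optional classification heads.

    ``n_diffusion``/``n_mt`` fix the signal layout; the active input
    channels and map features follow the ablation flags.
    """

    def __init__(self, n_diffusion: int, n_mt: int,
                 encoder_spec: EncoderSpec = EncoderSpec(),
                 flow_spec: FlowSpec = FlowSpec(),
                 ablation: tuple = (), seed: int = 0,
                 fingerprint: str = ""):
        unknown = set(ablation) - set(ABLATIONS)
        if unknown:
            raise ParameterError(f"unknown ablation flags: {sorted(unknown)}")
        if "diffusion_only" in ablation and "mt_only" in ablation:
            raise ParameterError("diffusion_only and mt_only are exclusive")
        rng = np.random.default_rng(seed)
        self.n_diffusion = n_diffusion
        self.n_mt = n_mt
        self.encoder_spec = encoder_spec
        self.flow_spec = flow_spec
        self.ablation = tuple(ablation)
        self.fingerprint = fingerprint
        self.stats = Standardization()

        if "diffusion_only" in ablation:
            self._sig_idx = np.arange(n_diffusion)
            self._map_idx = np.array(_DIFFUSION_MAPS)
        elif "mt_only" in ablation:
            self._sig_idx = np.arange(n_diffusion, n_diffusion + n_mt)
            self._map_idx = np.array(_MT_MAPS)
        else:
            self._sig_idx = np.arange(n_diffusion + n_mt)
            self._map_idx = np.arange(7)
        if "no_maps" in ablation:
            self._map_idx = np.array([], dtype=int)

        self.encoder = Encoder(self._sig_idx.size, encoder_spec, rng)
        self.n_context = encoder_spec.layer_widths[-1] + self._map_idx.size
        self.flow = ConditionalFlow(self.n_context, flow_spec, rng)
        if "no_multitask" in ablation:
            self.region_head = None
            self.group_head = None
        else:
            self.region_head = ClassifierHead(self.n_context, len(REGIONS), rng)
            self.group_head = ClassifierHead(self.n_context, len(GROUPS), rng)

    # -- context ---------------------------------------------------------
    def _check_x(self, x: np.ndarray):
        want = self.n_diffusion + self.n_mt
        if x.shape[-1] != want:
            raise ProtocolFormatError(
                f"signal vector has {x.shape[-1]} channels, model expects "
                f"{want} ({self.n_diffusion} diffusion + {self.n_mt} MT)")

    def _standardize_inputs(self, x, maps):
        x = np.atleast_2d(np.asarray(x, float))
        self._check_x(x)
        xs = (x[:, self._sig_idx] - self.stats.x_mean) / self.stats.x_std
        if self._map_idx.size:
            maps = np.atleast_2d(np.asarray(maps, float))
            if maps.shape[-1] != 7:
                raise ProtocolFormatError(
                    f"maps must provide 7 features, got {maps.shape[-1]}")
            ms = ((maps[:, self._map_idx] - self.stats.maps_mean)
                  / self.stats.maps_std)
        else:
            ms = np.zeros((x.shape[0], 0))
        return xs, ms

    def encode_context_np(self, x, maps) -> np.ndarray:
        """Deterministic (evaluation-mode) context vectors, (n, n_context)."""
        xs, ms = self._standardize_inputs(x, maps)
        enc = self.encoder.forward_np(xs)
        return np.concatenate([enc, ms], axis=1)

    def encode_context(self, x, maps, training: bool, rng=None) -> Tensor:
        xs, ms = self._standardize_inputs(x, maps)
        enc = self.encoder(Tensor(xs), training, rng)
        if ms.shape[1]:
            enc = Tensor.concat([enc, Tensor(ms)], axis=1)
        return enc

    # -- variable transform ----------------------------------------------
    def _to_u(self, d, g):
        d = np.asarray(d, float)
        g = np.asarray(g, float)
        if np.any(d <= 0) or np.any(g <= 0) or np.any(g >= 1):
            raise ParameterError("require d > 0 and 0 < g < 1")
        u = np.column_stack([np.log(d).ravel(),
                             (np.log(g) - np.log1p(-g)).ravel()])
        return (u - self.stats.u_mean) / self.stats.u_std

    def _log_jacobian(self, d, g):
        """log |du/d(d,g)|: standardization + log/logit corrections."""
        d = np.asarray(d, float).ravel()
        g = np.asarray(g, float).ravel()
        return (-np.log(self.stats.u_std).sum()
                - np.log(d) - np.log(g) - np.log1p(-g))

    def _from_u(self, u):
        v = u * self.stats.u_std + self.stats.u_mean
        d = np.exp(v[:, 0])
        g = 1.0 / (1.0 + np.exp(-v[:, 1]))
        return d, g

    # -- density API ------------------------------------------------------
    def log_density_np(self, d, g, context: np.ndarray) -> np.ndarray:
        """log p(d, g | context); ``context`` is (n, n_context) or (n_context,)."""
        u = self._to_u(d, g)
        ctx = np.atleast_2d(context)
        if ctx.shape[0] == 1 and u.shape[0] > 1:
            ctx = np.broadcast_to(ctx, (u.shape[0], ctx.shape[1]))
        out = self.flow.log_prob_np(u, ctx) + self._log_jacobian(d, g)
        if not np.all(np.isfinite(out)):
            bad = np.argwhere(~np.isfinite(out)).ravel()[:3]
            raise NumericalStabilityError(
                f"non-finite log-density at indices {bad.tolist()}")
        return out

    def sample_joint(self, n: int, context: np.ndarray, seed=None):
        """n seeded draws of (d, g) from p(. | context)."""
        if n == 0:
            return np.empty(0), np.empty(0)
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        ctx = np.atleast_2d(context)
        z = rng.standard_normal((n, 2))
        ctxn = np.broadcast_to(ctx, (n, ctx.shape[1])) if ctx.shape[0] == 1 else ctx
        u = self.flow.invert_np(z, ctxn)
        d, g = self._from_u(u)
        d = np.clip(d, 1e-6, self.stats.d_max)  # keep inside working rectangle
        g = np.clip(g, 1e-9, 1.0 - 1e-9)
        return d, g

    def nll_loss(self, u_batch: np.ndarray, ctx: Tensor,
                 log_jac: np.ndarray) -> Tensor:
        """Mean negative log-likelihood over all (d, g) samples of the batch.

        The printed objective sums over samples; the mean form divides by
        the batch size for optimizer-scale stability. ``log_jac`` carries
        the parameter-independent transform corrections so the loss value
        is the true NLL.
        """
        if u_batch.shape[0] == 0:
            raise ParameterError("empty batch")
        lp = self.flow.log_prob(Tensor(u_batch), ctx)
        loss = -(lp.mean()) - float(np.mean(log_jac))
        if not np.isfinite(loss.data):
            raise NumericalStabilityError("non-finite NLL; training aborted")
        return loss

    def classification_logits(self, ctx: Tensor):
        if self.region_head is None:
            raise ParameterError("classification heads absent (no_multitask)")
        return self.region_head(ctx), self.group_head(ctx)

    def classification_heads_np(self, context: np.ndarray):
        """(region probabilities, group probabilities) for given contexts."""
        if self.region_head is None:
            raise ParameterError("classification heads absent (no_multitask)")
        ctx = np.atleast_2d(context)
        return (softmax_np(self.region_head.forward_np(ctx)),
                softmax_np(self.group_head.forward_np(ctx)))

    # -- component access for freezing -----------------------------------
    def components(self) -> dict:
        out = {"encoder_layer_1": [self.encoder.l1, self.encoder.a1],
               "encoder_layer_2": [self.encoder.l2, self.encoder.a2,
                                   self.encoder.bn2],
               "encoder_layer_3": [self.encoder.l3, self.encoder.a3,
                                   self.encoder.bn3]}
        for i, blk in enumerate(self.flow.blocks):
            out[f"flow_block_{i + 1}"] = [blk]
        if self.region_head is not None:
            out["heads"] = [self.region_head, self.group_head]
        return out

    def component_parameters(self, names) -> list[Tensor]:
        comp = self.components()
        params = []
        for n in names:
            for m in comp[n]:
                params.extend(m.parameters())
        return params

    def parameter_hash(self, component: str) -> str:
        h = hashlib.sha256()
        for p in self.component_parameters([component]):
            h.update(p.data.tobytes())
        return h.hexdigest()[:16]

    # -- checkpointing -----------------------------------------------------
    def config_dict(self) -> dict:
        return {"n_diffusion": self.n_diffusion, "n_mt": self.n_mt,
                "encoder_spec": asdict(self.encoder_spec),
                "flow_spec": asdict(self.flow_spec),
                "ablation": list(self.ablation),
                "fingerprint": self.fingerprint,
                "stats": self.stats.to_dict()}

    def save(self, path) -> None:
        arrays = self.state_arrays()
        arrays["__config__"] = np.frombuffer(
            json.dumps(self.config_dict()).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path, expected_fingerprint: str | None = None,
             force: bool = False) -> "CNFM":
        with np.load(path, allow_pickle=False) as z:
            cfg = json.loads(bytes(z["__config__"]).decode())
            model = cls(cfg["n_diffusion"], cfg["n_mt"],
                        EncoderSpec(tuple(cfg["encoder_spec"]["layer_widths"]),
                                    cfg["encoder_spec"]["dropout_rate"]),
                        FlowSpec(**cfg["flow_spec"]),
                        ablation=tuple(cfg["ablation"]),
                        fingerprint=cfg["fingerprint"])
            model.stats = Standardization.from_dict(cfg["stats"])
            arrays = {k: z[k] for k in z.files if k != "__config__"}
        model.load_state_arrays(arrays)
        if (expected_fingerprint is not None
                and model.fingerprint != expected_fingerprint and not force):
            raise ProtocolFormatError(
                "checkpoint was trained for a different protocol "
                f"({model.fingerprint} != {expected_fingerprint}); pass "
                "force=True to override")
        return model


# ---------------------------------------------------------------------------
# evaluable density handle


class JointDensity:
    """A trained model bound to one fixed context: evaluable and sampleable."""

    def __init__(self, model: CNFM, context: np.ndarray):
        self.model = model
        self.context = np.atleast_2d(np.asarray(context, float))

    @property
    def d_max(self) -> float:
        return float(self.model.stats.d_max)

    def logpdf(self, d, g) -> np.ndarray:
        return self.model.log_density_np(d, g, self.context)

    def pdf(self, d, g) -> np.ndarray:
        return np.exp(self.logpdf(d, g))

    def grid(self, n_d: int = 200, n_g: int = 200):
        """(d_centers, g_centers, pdf values (n_d, n_g)) on the rectangle."""
        eps = 1e-6
        d = np.linspace(eps, self.d_max, n_d + 1)
        d = 0.5 * (d[:-1] + d[1:])
        g = np.linspace(eps, 1.0 - eps, n_g + 1)
        g = 0.5 * (g[:-1] + g[1:])
        D, G = np.meshgrid(d, g, indexing="ij")
        P = self.pdf(D.ravel(), G.ravel()).reshape(n_d, n_g)
        return d, g, P

    def normalization(self, n_d: int = 200, n_g: int = 200) -> float:
        """Quadrature integral of the density over the working rectangle."""
        d, g, P = self.grid(n_d, n_g)
        return float(np.trapezoid(np.trapezoid(P, g, axis=1), d))

    def mean(self, n_d: int = 200, n_g: int = 200):
        """(E[d], E[g]) by quadrature over the working rectangle."""
        d, g, P = self.grid(n_d, n_g)
        Z = np.trapezoid(np.trapezoid(P, g, axis=1), d)
        Ed = np.trapezoid(np.trapezoid(P * d[:, None], g, axis=1), d) / Z
        Eg = np.trapezoid(np.trapezoid(P * g[None, :], g, axis=1), d) / Z
        return float(Ed), float(Eg)

    def sample(self, n: int, seed=None):
        return self.model.sample_joint(n, self.context, seed)
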