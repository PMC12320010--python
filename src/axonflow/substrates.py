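"""Per-voxel axon populations standing in for EM-derived ground truth.

A *substrate* is the list of axons seen in one histology tile (the region
corresponding to one MRI voxel): inner diameters ``d_in`` in micrometers and
g-ratios ``g`` (inner / outer diameter). Only diameters and areas matter for
the forward MRI model, so no spatial packing is simulated.

The generator draws gamma-distributed diameters and scaled-beta g-ratios
coupled through a Gaussian copula with configurable rank correlation, with
per-voxel jitter of the population parameters so that voxels differ — the
heterogeneity a conditional density model must learn. Region and group labels
are assigned from a configurable label->parameter mapping so classification
heads are trainable on synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import EmptySubstrateError, InfeasibleSubstrateError, ParameterError

REGIONS = ("genu", "body", "splenium")
GROUPS = ("wildtype", "mutant")

#: Maximum admissible axon+myelin area fraction of a tile. Real white matter
#: packs to ~0.8; the generator trims populations beyond this.
MAX_PACKING_FRACTION = 0.85


@dataclass(frozen=True)
class Axon:
    """One axon: inner diameter (um) and g-ratio (inner/outer diameter)."""

    d_in: float
    g: float

    def __post_init__(self):
        if not self.d_in > 0:
            raise ParameterError(f"d_in must be > 0, got {self.d_in}")
        if not 0 < self.g <= 1:
            raise ParameterError(f"g must be in (0, 1], got {self.g}")

    @property
    def d_out(self) -> float:
        """Outer diameter including the myelin sheath (um)."""
        return self.d_in / self.g


@dataclass
class VoxelSubstrate:
    """The axon population of one tile / voxel.

    Stored as parallel arrays for speed; :meth:`axons` gives the object view.
    """

    d_in: np.ndarray  # um
    g: np.ndarray     # dimensionless, (0, 1]
    tile_side: float = 125.0  # um
    region_label: str | None = None
    group_label: str | None = None
    #: When True, MT simulation uses :attr:`mvf_frozen` instead of the
    #: geometric MVF (set by :func:`scale_diameters`).
    mvf_frozen: float | None = None

    def __post_init__(self):
        self.d_in = np.atleast_1d(np.asarray(self.d_in, dtype=float))
        self.g = np.atleast_1d(np.asarray(self.g, dtype=float))
        if self.d_in.shape != self.g.shape:
            raise ParameterError("d_in and g must have the same length")
        if self.d_in.size and (np.any(self.d_in <= 0) or np.any(self.g <= 0)
                               or np.any(self.g > 1)):
            raise ParameterError("require d_in > 0 and 0 < g <= 1")
        if self.region_label is not None and self.region_label not in REGIONS:
            raise ParameterError(f"region_label must be one of {REGIONS}")
        if self.group_label is not None and self.group_label not in GROUPS:
            raise ParameterError(f"group_label must be one of {GROUPS}")

    @property
    def n_axons(self) -> int:
        return int(self.d_in.size)

    @property
    def tile_area(self) -> float:
        return self.tile_side ** 2

    def axons(self) -> list[Axon]:
        return [Axon(d, g) for d, g in zip(self.d_in, self.g)]

    def pairs(self) -> np.ndarray:
        """(n, 2) array of (d_in, g)."""
        return np.column_stack([self.d_in, self.g])


@dataclass(frozen=True)
class LabelEffects:
    """Multiplicative/additive modifiers applied per (region, group).

    ``region_diameter_scale`` multiplies the voxel mean diameter;
    ``group_g_shift`` is added to the voxel mean g-ratio for the mutant
    group in the listed regions (mutants show lower g in genu and body).
    """

    region_diameter_scale: dict = field(default_factory=lambda: {
        "genu": 0.90, "body": 1.00, "splenium": 1.10})
    group_g_shift: dict = field(default_factory=lambda: {
        ("mutant", "genu"): -0.04, ("mutant", "body"): -0.04})


@dataclass(frozen=True)
class SubstrateParams:
    """Population-level generative law for voxel substrates.

    Defaults emulate a large-axon spinal-cord-like white-matter population:
    gamma diameters with mean ``diameter_gamma[0] * diameter_gamma[1]``
    (shape 3.0, scale 0.69 -> mean 2.07 um), scaled-beta g-ratios with mean
    0.70, rank correlation +0.4 between d and g, and an axon count whose
    per-voxel rate is uniform in ``n_axons`` (then capped by packing).
    """

    n_axons: tuple[int, int] = (500, 1100)      # uniform range of Poisson rate
    diameter_gamma: tuple[float, float] = (3.0, 2.07 / 3.0)  # (shape, scale), um
    g_beta: tuple[float, float] = (35.0, 15.0)  # Beta(a, b) on (0, 1)
    correlation: float = 0.4                    # Spearman rank correlation d~g
    tile_side: float = 125.0                    # um
    #: sd of the lognormal per-voxel jitter on the mean diameter
    voxel_mean_jitter: float = 0.12
    #: half-width of the uniform per-voxel jitter on the mean g-ratio
    voxel_g_jitter: float = 0.04
    seed: int = 0
    label_effects: LabelEffects | None = None
    assign_labels: bool = False

    def validate(self):
        sh, sc = self.diameter_gamma
        a, b = self.g_beta
        if min(sh, sc, a, b) <= 0:
            raise ParameterError("distribution parameters must be > 0")
        if not abs(self.correlation) <= 1:
            raise ParameterError("|correlation| must be <= 1")
        if self.n_axons[0] < 1 or self.n_axons[1] < self.n_axons[0]:
            raise ParameterError("n_axons range must be ordered and >= 1")
        if self.tile_side <= 0:
            raise ParameterError("tile_side must be > 0")


def _copula_rho(rank_corr: float) -> float:
    # Gaussian-copula Pearson parameter reproducing a target Spearman rho
    return 2.0 * np.sin(np.pi * rank_corr / 6.0)


def _sample_voxel(rng: np.random.Generator, params: SubstrateParams,
                  region: str | None, group: str | None) -> VoxelSubstrate:
    shape, scale = params.diameter_gamma
    a, b = params.g_beta

    mean_d = shape * scale
    # mean-preserving lognormal jitter of the voxel mean diameter
    sj = params.voxel_mean_jitter
    mean_scale = float(np.exp(rng.normal(-0.5 * sj * sj, sj)))
    vox_shape = shape * rng.uniform(0.8, 1.25)
    if params.label_effects is not None and region is not None:
        mean_scale *= params.label_effects.region_diameter_scale.get(region, 1.0)
    vox_scale = mean_d * mean_scale / vox_shape

    g_mean = a / (a + b) + rng.uniform(-params.voxel_g_jitter,
                                       params.voxel_g_jitter)
    if params.label_effects is not None and group is not None:
        g_mean += params.label_effects.group_g_shift.get((group, region), 0.0)
    g_mean = float(np.clip(g_mean, 0.05, 0.98))
    nu = a + b  # keep the beta concentration, move its mean
    va, vb = g_mean * nu, (1.0 - g_mean) * nu

    lo, hi = params.n_axons
    if lo == hi:  # degenerate: deterministic count
        n = int(lo)
    else:
        n = max(1, int(rng.poisson(rng.uniform(lo, hi))))
    # Gaussian copula draw
    rho = _copula_rho(params.correlation)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    from scipy import stats
    u = stats.norm.cdf(z)
    d = stats.gamma.ppf(u[:, 0], vox_shape, scale=vox_scale)
    g = stats.beta.ppf(u[:, 1], va, vb)
    d = np.clip(d, 1e-3, None)
    g = np.clip(g, 1e-3, 1.0)

    # enforce the packing cap by trimming the population (area-limited count)
    outer_area = np.pi * (d / (2.0 * g)) ** 2
    budget = MAX_PACKING_FRACTION * params.tile_side ** 2
    csum = np.cumsum(outer_area)
    keep = int(np.searchsorted(csum, budget, side="right"))
    if keep < 1:
        keep = 1
    d, g = d[:keep], g[:keep]
    return VoxelSubstrate(d, g, tile_side=params.tile_side,
                          region_label=region, group_label=group)


def sample_population(params: SubstrateParams, n_voxels: int,
                      seed: int | None = None) -> list[VoxelSubstrate]:
    """Draw ``n_voxels`` substrates from the population law.

    Reproducible for a fixed seed (``seed`` overrides ``params.seed``).
    """
    params.validate()
    if n_voxels < 1:
        raise ParameterError("n_voxels must be >= 1")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    voxels = []
    for i in range(n_voxels):
        if params.assign_labels:
            region = REGIONS[i % len(REGIONS)]
            group = GROUPS[(i // len(REGIONS)) % len(GROUPS)]
        else:
            region = group = None
        voxels.append(_sample_voxel(rng, params, region, group))
    return voxels


def volume_fractions(substrate: VoxelSubstrate) -> tuple[float, float, float]:
    """(AVF, MVF, ECF) of a substrate from summed cross-sectional areas.

    AVF sums inner-disc areas, MVF sums myelin annulus areas
    pi*((d/2g)^2 - (d/2)^2), and ECF = 1 - AVF - MVF.
    """
    if substrate.n_axons == 0:
        raise EmptySubstrateError("substrate has no axons")
    area = substrate.tile_area
    inner = np.pi * (substrate.d_in / 2.0) ** 2
    outer = np.pi * (substrate.d_in / (2.0 * substrate.g)) ** 2
    avf = float(inner.sum() / area)
    mvf = float((outer - inner).sum() / area)
    if avf + mvf > 1.0 + 1e-12:
        raise InfeasibleSubstrateError(
            f"axon+myelin area fraction {avf + mvf:.3f} exceeds tile area")
    return avf, mvf, 1.0 - avf - mvf


def scale_diameters(substrate: VoxelSubstrate, factor: float) -> VoxelSubstrate:
    """Rescale every inner diameter by ``factor``; g-ratios unchanged.

    Records the pre-scaling MVF in ``mvf_frozen`` so MT simulation can hold
    the myelin content constant while the diffusion geometry shrinks
    (matching populations with a 2.07 um mean scaled by 0.15 to 0.31 um).
    """
    if not factor > 0:
        raise ParameterError("factor must be > 0")
    frozen = substrate.mvf_frozen
    if frozen is None and factor != 1.0:
        frozen = volume_fractions(substrate)[1]
    return replace(substrate, d_in=substrate.d_in * factor,
                   g=substrate.g.copy(), mvf_frozen=frozen)


def filter_population(voxels: list[VoxelSubstrate],
                      min_axons: int = 400) -> list[VoxelSubstrate]:
    """Keep voxels with at least ``min_axons`` axons (inclusive), order kept."""
    if min_axons < 0:
        raise ParameterError("min_axons must be >= 0")
    return [v for v in voxels if v.n_axons >= min_axons]


# ---------------------------------------------------------------------------
# serialization


def to_frame(voxels: list[VoxelSubstrate]) -> pd.DataFrame:
    """One row per axon: voxel_id, d_in_um, g, region, group, tile_side_um."""
    rows = []
    for i, v in enumerate(voxels):
        rows.append(pd.DataFrame({
            "voxel_id": i, "d_in_um": v.d_in, "g": v.g,
            "region": v.region_label or "", "group": v.group_label or "",
            "tile_side_um": v.tile_side,
            "mvf_frozen": np.nan if v.mvf_frozen is None else v.mvf_frozen,
        }))
    return pd.concat(rows, ignore_index=True)


def from_frame(df: pd.DataFrame) -> list[VoxelSubstrate]:
    def _label(v):
        return None if (pd.isna(v) or v == "") else str(v)

    voxels = []
    for _, grp in df.groupby("voxel_id", sort=True):
        frozen = grp["mvf_frozen"].iloc[0]
        voxels.append(VoxelSubstrate(
            grp["d_in_um"].to_numpy(), grp["g"].to_numpy(),
            tile_side=float(grp["tile_side_um"].iloc[0]),
            region_label=_label(grp["region"].iloc[0]),
            group_label=_label(grp["group"].iloc[0]),
            mvf_frozen=None if pd.isna(frozen) else float(frozen)))
    return voxels


def save_text(voxels: list[VoxelSubstrate], path) -> None:
    to_frame(voxels).to_csv(path, sep="\t", index=False, float_format="%.17g")


def load_text(path) -> list[VoxelSubstrate]:
    return from_frame(pd.read_csv(path, sep="\t",
                                  keep_default_na=False,
                                  na_values=[""],
                                  float_precision="round_trip",
                                  dtype={"region": str, "group": str}))


def save_npz(voxels: list[VoxelSubstrate], path) -> None:
    """Compact binary container (one flat array pair + voxel offsets)."""
    offsets = np.cumsum([0] + [v.n_axons for v in voxels])
    if not hasattr(path, "write"):
        path = open(path, "wb")  # keep the caller's exact filename
    np.savez_compressed(
        path,
        d_in=np.concatenate([v.d_in for v in voxels]),
        g=np.concatenate([v.g for v in voxels]),
        offsets=offsets,
        tile_side=np.array([v.tile_side for v in voxels]),
        region=np.array([v.region_label or "" for v in voxels]),
        group=np.array([v.group_label or "" for v in voxels]),
        mvf_frozen=np.array([np.nan if v.mvf_frozen is None else v.mvf_frozen
                             for v in voxels]))


def load_npz(path) -> list[VoxelSubstrate]:
    with np.load(path, allow_pickle=False) as z:
        offs = z["offsets"]
        voxels = []
        for i in range(len(offs) - 1):
            sl = slice(offs[i], offs[i + 1])
            frozen = float(z["mvf_frozen"][i])
            voxels.append(VoxelSubstrate(
                z["d_in"][sl], z["g"][sl], tile_side=float(z["tile_side"][i]),
                region_label=str(z["region"][i]) or None,
                group_label=str(z["group"][i]) or None,
                mvf_frozen=None if np.isnan(frozen) else frozen))
    return voxels
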