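"""Synthetic z-stacks with planted open/closed chromatin domains.

The generator emulates the qualitative contrasts that distinguish the two
chromatin states in super-resolution data: closed (B) domains are dense,
elongated/asymmetric, high-material objects; open (A) domains are
sparser, near-spherical, lower-material objects.  Blobs are rasterized
randomly rotated ellipsoids, defined in physical nm so the same
population can be imaged at different batch resolutions; "open" sparsity
comes from Bernoulli thinning of the ellipsoid interior.  Intensities are
drawn on the more-chromatin-is-high ("material") scale and converted to
the stack's polarity at write time (inverted for dark-is-signal).
Additive Gaussian background noise is clipped to the bit depth.

Per-batch affine distortions (gain, offset) of the written intensities
plus per-batch voxel sizes reproduce the batch effects that the per-batch
normalization step is meant to remove.

A feature-space companion (:func:`make_feature_dataset`) plants a small
number of informative Gaussian features among pure noise columns for
exercising the selection stage in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stack_io import BRIGHT_IS_SIGNAL, DARK_IS_SIGNAL, ImageStack

__all__ = [
    "DomainPopulation",
    "SyntheticSpec",
    "generate_domain",
    "generate_dataset",
    "make_feature_dataset",
    "match_domains_to_truth",
]

_MAX16 = 65535


@dataclass
class DomainPopulation:
    """Blob parameters for one chromatin state, on the material scale."""

    radius_range_nm: tuple[float, float]
    elongation_range: tuple[float, float]  # major/minor axis ratio
    fill: float  # Bernoulli keep probability inside the ellipsoid
    intensity_mean: float
    intensity_sd: float

    def __post_init__(self):
        if self.radius_range_nm[0] <= 0:
            raise ValueError("blob radius must be positive")
        if not (0 < self.fill <= 1):
            raise ValueError("fill density must be in (0, 1]")


@dataclass
class SyntheticSpec:
    """Study conditions for a planted-truth dataset.

    Defaults describe a two-batch dark-is-signal experiment with 200
    domains of each state, batch voxel sizes matching the two probe-based
    acquisition rounds (7x7x30 and 5x5x30 nm), and a mild per-batch
    gain/offset distortion on top of the resolution difference.
    """

    n_open: int = 200
    n_closed: int = 200
    n_batches: int = 2
    domains_per_stack: int = 2
    stack_shape: tuple[int, int, int] = (14, 64, 64)  # (nz, ny, nx)
    voxel_sizes: tuple = ((30.0, 7.0, 7.0), (30.0, 5.0, 5.0))
    polarity: str = DARK_IS_SIGNAL
    open_params: DomainPopulation = field(
        default_factory=lambda: DomainPopulation(
            radius_range_nm=(22.0, 42.0),
            elongation_range=(1.0, 1.2),
            fill=0.6,
            intensity_mean=18000.0,
            intensity_sd=4000.0,
        )
    )
    closed_params: DomainPopulation = field(
        default_factory=lambda: DomainPopulation(
            radius_range_nm=(28.0, 48.0),
            elongation_range=(1.8, 2.4),
            fill=1.0,
            intensity_mean=32000.0,
            intensity_sd=4000.0,
        )
    )
    background_level: float = 2000.0  # material scale
    noise_sd: float = 0.02 * _MAX16
    min_separation_voxels: float = 8.0
    batch_effects: dict = field(default_factory=lambda: {"batch2": (0.9, 3000.0)})
    seed: int = 0

    def __post_init__(self):
        if not (
            self.closed_params.fill > self.open_params.fill
            and self.closed_params.intensity_mean > self.open_params.intensity_mean
        ):
            raise ValueError(
                "the closed population must be denser and higher-material than the open one"
            )
        if self.polarity not in (DARK_IS_SIGNAL, BRIGHT_IS_SIGNAL):
            raise ValueError(f"bad polarity {self.polarity!r}")

    def batch_ids(self) -> list[str]:
        return [f"batch{j + 1}" for j in range(self.n_batches)]


def _random_rotation(rng) -> np.ndarray:
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def generate_domain(kind: str, params: DomainPopulation, voxel_size, seed):
    """One random blob: ``(offsets, intensities, radius_nm)``.

    ``offsets`` are integer (z, y, x) voxel offsets relative to the blob
    center on the anisotropic grid with spacing ``voxel_size`` (nm);
    ``intensities`` are material-scale values.  Same seed, same blob.
    """
    rng = np.random.default_rng(seed)
    r = rng.uniform(*params.radius_range_nm)
    e = rng.uniform(*params.elongation_range)
    # prolate ellipsoid with volume-preserving axes: major r*e^(2/3), minor r/e^(1/3)
    semi = np.array([r * e ** (2 / 3), r / e ** (1 / 3), r / e ** (1 / 3)])
    rot = _random_rotation(rng)
    d = np.asarray(voxel_size, dtype=float)
    half = np.ceil(semi.max() / d).astype(int)
    if np.any(half < 1):
        raise ValueError("blob radius below one voxel at this resolution")
    grid = np.stack(
        np.meshgrid(*(np.arange(-h, h + 1) for h in half), indexing="ij"), axis=-1
    ).reshape(-1, 3)
    phys = grid * d  # nm
    local = phys @ rot  # rotate into the ellipsoid frame
    inside = np.sum((local / semi) ** 2, axis=1) <= 1.0
    offsets = grid[inside]
    if params.fill < 1.0:
        keep = rng.random(len(offsets)) < params.fill
        # always keep the center voxel so the blob cannot vanish
        keep |= np.all(offsets == 0, axis=1)
        offsets = offsets[keep]
    intensities = np.clip(
        rng.normal(params.intensity_mean, params.intensity_sd, size=len(offsets)),
        0,
        _MAX16,
    )
    return offsets, intensities, float(semi.max())


def _place_blobs(spec, rng, voxel_size, kinds, stack_index):
    """Place blob centers with pairwise physical separation; bounded retries."""
    nz, ny, nx = spec.stack_shape
    d = np.asarray(voxel_size)
    sep_nm = spec.min_separation_voxels * d[2]
    centers, blobs = [], []
    for kind in kinds:
        params = spec.closed_params if kind == "B" else spec.open_params
        placed = False
        # a crowded draw (e.g. two maximal blobs) may be unplaceable even
        # when the spec is fine on average: redraw the blob a few times
        for _ in range(5):
            seed = int(rng.integers(2**31 - 1))
            offsets, intens, r = generate_domain(kind, params, voxel_size, seed)
            margin = np.abs(offsets).max(axis=0) + 2
            if np.any(2 * margin + 2 >= np.array(spec.stack_shape)):
                raise ValueError(
                    f"blob radius {r:.0f} nm does not fit stack shape {spec.stack_shape} "
                    f"at voxel size {tuple(d)}"
                )
            for _ in range(200):
                c = np.array(
                    [rng.integers(m, s - m) for m, s in zip(margin, spec.stack_shape)]
                )
                ok = all(
                    np.linalg.norm((c - c2) * d) > (r + r2 + sep_nm)
                    for c2, r2 in centers
                )
                if ok:
                    centers.append((c, r))
                    blobs.append((kind, c, offsets, intens, r))
                    placed = True
                    break
            if placed:
                break
        if not placed:
            raise ValueError(
                f"could not place {len(kinds)} blobs in stack {stack_index}: "
                "spec is overcrowded"
            )
    return blobs


def generate_dataset(spec: SyntheticSpec, seed=None):
    """Generate stacks plus a ground-truth table.

    Returns ``(stacks, truth)`` where ``truth`` has one row per planted
    domain: stack_id, batch_id, kind (A/B), physical centroid (nm) within
    the stack, and blob radius.  ``seed=None`` uses ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    kinds = ["A"] * spec.n_open + ["B"] * spec.n_closed
    rng.shuffle(kinds)
    per_stack = spec.domains_per_stack
    batch_ids = spec.batch_ids()

    stacks, truth = [], []
    stack_index = 0
    for start in range(0, len(kinds), per_stack):
        stack_kinds = kinds[start : start + per_stack]
        batch = batch_ids[stack_index % spec.n_batches]
        voxel_size = spec.voxel_sizes[stack_index % spec.n_batches]
        blobs = _place_blobs(spec, rng, voxel_size, stack_kinds, stack_index)

        material = np.full(spec.stack_shape, spec.background_level, dtype=float)
        for kind, c, offsets, intens, r in blobs:
            zyx = offsets + c
            material[tuple(zyx.T)] = intens
        raw = material if spec.polarity == BRIGHT_IS_SIGNAL else _MAX16 - material
        gain, offset = spec.batch_effects.get(batch, (1.0, 0.0))
        raw = raw * gain + offset
        raw = raw + rng.normal(0.0, spec.noise_sd, size=raw.shape)
        raw = np.clip(np.rint(raw), 0, _MAX16).astype(np.uint16)

        stack_id = f"stack{stack_index:04d}"
        stacks.append(
            ImageStack(
                voxels=raw,
                voxel_size=voxel_size,
                polarity=spec.polarity,
                batch_id=batch,
                stack_id=stack_id,
            )
        )
        d = np.asarray(voxel_size)
        for domain_i, (kind, c, offsets, intens, r) in enumerate(blobs, start=1):
            center_nm = c * d
            truth.append(
                {
                    "stack_id": stack_id,
                    "batch_id": batch,
                    "kind": kind,
                    "center_z_nm": center_nm[0],
                    "center_y_nm": center_nm[1],
                    "center_x_nm": center_nm[2],
                    "radius_nm": r,
                    "n_voxels": len(offsets),
                }
            )
        stack_index += 1
    return stacks, pd.DataFrame(truth)


def match_domains_to_truth(feature_table: pd.DataFrame, domains, truth: pd.DataFrame):
    """Planted kind for each segmented domain, by nearest centroid (nm).

    Returns an array aligned with ``feature_table`` rows; domains farther
    than twice the planted radius from every truth centroid get ``None``.
    """
    centroids = {}
    for d in domains:
        com = d.voxel_coords.mean(axis=0) * d.voxel_size_iso
        centroids[(d.stack_id, d.domain_id)] = com
    kinds = []
    for _, row in feature_table.iterrows():
        com = centroids[(row["stack_id"], row["domain_id"])]
        cand = truth[truth["stack_id"] == row["stack_id"]]
        if cand.empty:
            kinds.append(None)
            continue
        pts = cand[["center_z_nm", "center_y_nm", "center_x_nm"]].to_numpy()
        dist = np.linalg.norm(pts - com, axis=1)
        j = int(np.argmin(dist))
        kinds.append(cand.iloc[j]["kind"] if dist[j] <= 2 * cand.iloc[j]["radius_nm"] else None)
    return np.array(kinds, dtype=object)


def make_feature_dataset(
    n: int = 400,
    n_features: int = 19,
    n_informative: int = 2,
    effect_size: float = 2.0,
    closed_fraction: float = 0.5,
    seed=None,
):
    """Feature-space dataset with planted informative columns.

    Classes are Gaussian; informative columns differ in mean by
    ``effect_size`` standard deviations, the rest are pure noise.
    Returns ``(X, y, informative_names)`` with y coded 'A'/'B'.
    """
    rng = np.random.default_rng(seed)
    n_closed = int(round(n * closed_fraction))
    y = np.array(["B"] * n_closed + ["A"] * (n - n_closed))
    rng.shuffle(y)
    X = rng.normal(size=(n, n_features))
    informative = [f"f{j + 1}" for j in range(n_informative)]
    X[:, :n_informative] += effect_size * (y == "B")[:, None]
    cols = [f"f{j + 1}" for j in range(n_features)]
    return pd.DataFrame(X, columns=cols), y, informative
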