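"""Image-stack and experiment-configuration I/O.

A stack is a single multi-page grayscale TIFF (one page per z-slice) with
three pieces of metadata that the rest of the pipeline needs: the physical
voxel size in nm, the signal polarity (whether chromatin appears dark, as
in 3D-EMISH, or bright, as in 3D-SIM), and a batch identifier used for
batch-effect removal.  Experiment configuration is a single JSON document.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "DARK_IS_SIGNAL",
    "BRIGHT_IS_SIGNAL",
    "POLARITIES",
    "ImageStack",
    "StackEntry",
    "ExperimentConfig",
    "read_stack",
    "write_stack",
    "load_config",
    "write_table",
]

DARK_IS_SIGNAL = "dark_is_signal"
BRIGHT_IS_SIGNAL = "bright_is_signal"
POLARITIES = (DARK_IS_SIGNAL, BRIGHT_IS_SIGNAL)


@dataclass
class ImageStack:
    """A 3D grayscale image with physical and experimental metadata.

    ``voxels`` is indexed ``(z, y, x)``; ``voxel_size`` is the matching
    ``(dz, dy, dx)`` in nm.  Intensities live on the declared bit-depth
    scale (default 16-bit, 0..65535); 8-bit input is upcast without
    rescaling because the fixed intensity thresholds used downstream are
    absolute 16-bit values.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    polarity: str
    batch_id: str
    stack_id: str = ""
    bit_depth: int = 16

    def __post_init__(self):
        v = np.asarray(self.voxels)
        if v.ndim == 2:
            v = v[np.newaxis]
        if v.ndim != 3:
            raise ValueError(f"voxels must be 3D (z, y, x); got ndim={v.ndim}")
        if v.shape[0] < 1 or v.shape[1] < 2 or v.shape[2] < 2:
            raise ValueError(f"stack too small: shape {v.shape}, need >=1 slice of >=2x2")
        self.voxels = v
        self.voxel_size = tuple(float(s) for s in self.voxel_size)
        if len(self.voxel_size) != 3 or any(s <= 0 for s in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive nm values, got {self.voxel_size}")
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}, got {self.polarity!r}")
        if v.size and (float(v.min()) < 0 or float(v.max()) > self.max_scale):
            raise ValueError(
                f"intensities outside [0, {self.max_scale}] for bit depth {self.bit_depth}"
            )

    @property
    def max_scale(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def with_voxels(self, voxels, voxel_size=None) -> "ImageStack":
        """Copy of this stack with new voxel data (metadata preserved)."""
        return ImageStack(
            voxels=voxels,
            voxel_size=self.voxel_size if voxel_size is None else voxel_size,
            polarity=self.polarity,
            batch_id=self.batch_id,
            stack_id=self.stack_id,
            bit_depth=self.bit_depth,
        )


def read_stack(path, voxel_size, polarity, batch_id, stack_id=None, bit_depth=16) -> ImageStack:
    """Read a multi-page grayscale TIFF into an :class:`ImageStack`.

    Pages map to z-slices in file order.  Raises ``FileNotFoundError`` for a
    missing file and ``ValueError`` for non-grayscale data.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such stack: {path}")
    voxels = tifffile.imread(str(path))
    if voxels.ndim == 2:
        voxels = voxels[np.newaxis]
    if voxels.ndim != 3:
        raise ValueError(f"{path}: expected grayscale pages, got array of ndim {voxels.ndim}")
    if voxels.dtype == np.uint8:
        voxels = voxels.astype(np.uint16)  # absolute upcast, no rescaling
    return ImageStack(
        voxels=voxels,
        voxel_size=voxel_size,
        polarity=polarity,
        batch_id=str(batch_id),
        stack_id=stack_id if stack_id is not None else path.stem,
        bit_depth=bit_depth,
    )


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as a multi-page grayscale TIFF (lossless round-trip)."""
    v = stack.voxels
    if not np.issubdtype(v.dtype, np.integer):
        v = np.clip(np.rint(v), 0, stack.max_scale)
    v = v.astype(np.uint16 if stack.bit_depth > 8 else np.uint8)
    tifffile.imwrite(str(path), v)


@dataclass
class StackEntry:
    path: str
    voxel_size: tuple[float, float, float]
    polarity: str
    batch_id: str


@dataclass
class ExperimentConfig:
    """Everything a full run needs, loadable from one JSON file."""

    stacks: list[StackEntry] = field(default_factory=list)
    smoothing_sigma_nm: float | None = None  # None -> one in-plane voxel per stack
    threshold_method: str = "multiotsu"  # "multiotsu" | "otsu" | "fixed"
    fixed_threshold: float | None = None
    min_domain_voxels: int = 30
    intensity_thresholds: tuple[float, float] = (24000.0, 30000.0)
    split_fraction: float = 0.7
    cv_folds: int = 10
    lambda_policy: str = "one_se"  # "one_se" | "fixed"
    lambda_value: float | None = None
    n_bootstrap: int = 100
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.split_fraction < 1):
            raise ValueError(f"split_fraction must be in (0, 1), got {self.split_fraction}")
        if self.cv_folds < 2:
            raise ValueError(f"cv_folds must be >= 2, got {self.cv_folds}")
        if self.min_domain_voxels < 1:
            raise ValueError(f"min_domain_voxels must be >= 1, got {self.min_domain_voxels}")
        if self.threshold_method not in ("multiotsu", "otsu", "fixed"):
            raise ValueError(
                f"threshold_method must be 'multiotsu', 'otsu' or 'fixed', got {self.threshold_method!r}"
            )
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("threshold_method 'fixed' requires fixed_threshold")
        if self.lambda_policy not in ("one_se", "fixed"):
            raise ValueError(f"lambda_policy must be 'one_se' or 'fixed', got {self.lambda_policy!r}")
        if self.lambda_policy == "fixed" and self.lambda_value is None:
            raise ValueError("lambda_policy 'fixed' requires lambda_value")
        self.intensity_thresholds = tuple(float(t) for t in self.intensity_thresholds)
        if len(self.intensity_thresholds) != 2:
            raise ValueError("intensity_thresholds must be a pair")
        polarities = {s.polarity for s in self.stacks}
        if len(polarities) > 1:
            raise ValueError(f"all stacks in one analysis must share polarity; got {polarities}")
        for s in self.stacks:
            if s.polarity not in POLARITIES:
                raise ValueError(f"stacks: bad polarity {s.polarity!r}")
            if any(d <= 0 for d in s.voxel_size):
                raise ValueError(f"stacks: voxel_size must be positive, got {s.voxel_size}")


_CONFIG_KEYS = {f.name for f in dataclasses.fields(ExperimentConfig)}
_STACK_KEYS = {f.name for f in dataclasses.fields(StackEntry)}


def load_config(path) -> ExperimentConfig:
    """Load an :class:`ExperimentConfig` from JSON; unknown keys are rejected."""
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"{path}: malformed JSON config: {e}") from e
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config root must be an object")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
    stacks = []
    for i, s in enumerate(raw.pop("stacks", [])):
        bad = set(s) - _STACK_KEYS
        if bad:
            raise ValueError(f"{path}: stacks[{i}]: unknown keys {sorted(bad)}")
        s = dict(s)
        s["voxel_size"] = tuple(s["voxel_size"])
        s["batch_id"] = str(s["batch_id"])
        stacks.append(StackEntry(**s))
    if "intensity_thresholds" in raw:
        raw["intensity_thresholds"] = tuple(raw["intensity_thresholds"])
    return ExperimentConfig(stacks=stacks, **raw)


def write_table(rows, path) -> None:
    """Write tabular records to CSV with a stable column order.

    ``rows`` may be a DataFrame or a list of dicts sharing a schema.
    Numeric fields round-trip at full precision (shortest-repr floats).
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        df = pd.DataFrame(rows, columns=list(rows[0].keys()) if rows else None)
    os.makedirs(Path(path).parent or Path("."), exist_ok=True)
    df.to_csv(path, index=False)
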