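"""Morphological parameter space of the idealized left coronary bifurcation.

A bifurcation model is described by five parameters: the diameters of the
left main (LM), left circumflex (LCx) and left anterior descending (LAD)
arteries, the LM-LAD bend angle gamma (180 deg = straight continuation) and
the LAD-LCx opening angle alpha.  This module samples model populations from
the admissible ranges and builds reproducible train/validation/test splits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import qmc

__all__ = [
    "ParamRanges",
    "MorphologyParams",
    "SplitManifest",
    "TABLE_RANGES",
    "sample_morphologies",
    "make_splits",
]


class ConfigurationError(ValueError):
    """Raised for invalid parameter ranges or split configurations."""


@dataclass(frozen=True)
class ParamRanges:
    """Admissible intervals for the five morphological parameters.

    Diameters in mm, angles in degrees.  ``gamma`` is the LM-LAD angle
    (values near 180 deg mean the LAD continues the LM almost straight);
    ``alpha`` is the opening angle between the two daughter branches.
    """

    d_lm_min: float = 2.18
    d_lm_max: float = 4.18
    d_lcx_min: float = 1.5
    d_lcx_max: float = 3.5
    d_lad_min: float = 1.5
    d_lad_max: float = 3.5
    gamma_min: float = 112.75
    gamma_max: float = 172.75
    alpha_min: float = 15.0
    alpha_max: float = 130.0

    def __post_init__(self) -> None:
        for name in ("d_lm", "d_lcx", "d_lad", "gamma", "alpha"):
            lo = getattr(self, f"{name}_min")
            hi = getattr(self, f"{name}_max")
            # degenerate (lo == hi) tolerated for point designs
            if lo > hi:
                raise ConfigurationError(f"{name}: min {lo} > max {hi}")
        if self.d_lm_min <= 0 or self.d_lcx_min <= 0 or self.d_lad_min <= 0:
            raise ConfigurationError("diameters must be positive")
        for ang in ("gamma", "alpha"):
            lo, hi = getattr(self, f"{ang}_min"), getattr(self, f"{ang}_max")
            if lo <= 0.0 or hi >= 180.0:
                raise ConfigurationError(f"{ang} range must lie in (0, 180) deg")

    def as_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array(
            [self.d_lm_min, self.d_lcx_min, self.d_lad_min, self.gamma_min, self.alpha_min]
        )
        hi = np.array(
            [self.d_lm_max, self.d_lcx_max, self.d_lad_max, self.gamma_max, self.alpha_max]
        )
        return lo, hi


#: Published admissible ranges for healthy left coronary bifurcations.
TABLE_RANGES = ParamRanges()


@dataclass(frozen=True)
class MorphologyParams:
    """One bifurcation model: three diameters (mm) and two angles (deg)."""

    d_lm: float
    d_lcx: float
    d_lad: float
    gamma: float
    alpha: float
    model_id: str = ""

    def validate(self, ranges: ParamRanges) -> None:
        lo, hi = ranges.as_bounds()
        vals = np.array([self.d_lm, self.d_lcx, self.d_lad, self.gamma, self.alpha])
        if np.any(vals < lo - 1e-12) or np.any(vals > hi + 1e-12):
            raise ConfigurationError(f"{self.model_id}: parameters outside ranges")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MorphologyParams":
        return cls(**d)


def sample_morphologies(
    ranges: ParamRanges,
    n: int,
    seed: int,
    method: str = "uniform",
    id_prefix: str = "model",
) -> list[MorphologyParams]:
    """Draw ``n`` morphological parameter vectors from ``ranges``.

    ``method`` is ``"uniform"`` (independent uniform per parameter) or
    ``"lhs"`` (scrambled Latin hypercube for better space filling).  Output
    is deterministic for a given ``(ranges, n, seed, method)``.
    """
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    lo, hi = ranges.as_bounds()
    if method == "uniform":
        rng = np.random.default_rng(seed)
        u = rng.random((n, 5))
    elif method == "lhs":
        sampler = qmc.LatinHypercube(d=5, seed=seed)
        u = sampler.random(n)
    else:
        raise ConfigurationError(f"unknown sampling method {method!r}")
    vals = lo + u * (hi - lo)
    width = len(str(max(n - 1, 1)))
    out = []
    for i in range(n):
        p = MorphologyParams(
            d_lm=float(vals[i, 0]),
            d_lcx=float(vals[i, 1]),
            d_lad=float(vals[i, 2]),
            gamma=float(vals[i, 3]),
            alpha=float(vals[i, 4]),
            model_id=f"{id_prefix}_{i:0{width}d}",
        )
        out.append(p)
    return out


@dataclass
class SplitManifest:
    """Reproducible dataset partition plus dataset-global label statistics.

    ``tawss_global_max``/``min`` are the extreme TAWSS values over *all*
    generated models; they are the normalization constants of the NAME
    metric and of network target scaling, and are filled in by dataset
    generation.
    """

    test_ids: list[str]
    val_ids: list[str]
    train_ids: list[str]
    seed: int
    tawss_global_max: float | None = None
    tawss_global_min: float | None = None
    params: dict[str, dict] = field(default_factory=dict)

    @property
    def all_ids(self) -> list[str]:
        return self.test_ids + self.val_ids + self.train_ids

    def split_of(self, model_id: str) -> str:
        if model_id in set(self.test_ids):
            return "test"
        if model_id in set(self.val_ids):
            return "val"
        return "train"

    def morphology(self, model_id: str) -> MorphologyParams:
        return MorphologyParams.from_dict(self.params[model_id])

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "splits": {
                "test": self.test_ids,
                "val": self.val_ids,
                "train": self.train_ids,
            },
            "tawss_global_max": self.tawss_global_max,
            "tawss_global_min": self.tawss_global_min,
            "params": self.params,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "SplitManifest":
        d = json.loads(Path(path).read_text())
        return cls(
            test_ids=d["splits"]["test"],
            val_ids=d["splits"]["val"],
            train_ids=d["splits"]["train"],
            seed=d["seed"],
            tawss_global_max=d["tawss_global_max"],
            tawss_global_min=d["tawss_global_min"],
            params=d.get("params", {}),
        )


def make_splits(
    model_ids: Sequence[str],
    batch_size: int = 300,
    test_per_batch: int = 60,
    val_frac: float = 0.10,
    seed: int = 0,
    morphologies: Iterable[MorphologyParams] = (),
) -> SplitManifest:
    """Partition ``model_ids`` into test/val/train sets.

    The test set takes ``test_per_batch`` ids uniformly at random (seeded)
    from each consecutive batch of ``batch_size`` ids; the validation set is
    then ``val_frac`` of the remaining pool (round-half-to-even).
    """
    n = len(model_ids)
    if n == 0 or n % batch_size != 0:
        raise ConfigurationError(
            f"number of models ({n}) not divisible by batch size ({batch_size})"
        )
    if not 0 <= test_per_batch < batch_size:
        raise ConfigurationError(
            f"test_per_batch ({test_per_batch}) must be in [0, batch_size)"
        )
    if not 0.0 <= val_frac < 1.0:
        raise ConfigurationError(f"val_frac ({val_frac}) must be in [0, 1)")

    rng = np.random.default_rng(seed)
    ids = list(model_ids)
    test: list[str] = []
    pool: list[str] = []
    for start in range(0, n, batch_size):
        batch = ids[start : start + batch_size]
        pick = rng.choice(batch_size, size=test_per_batch, replace=False)
        mask = np.zeros(batch_size, dtype=bool)
        mask[pick] = True
        test.extend(b for b, m in zip(batch, mask) if m)
        pool.extend(b for b, m in zip(batch, mask) if not m)

    n_val = int(np.round(val_frac * len(pool)))  # numpy rounds half to even
    val_pick = rng.choice(len(pool), size=n_val, replace=False)
    vmask = np.zeros(len(pool), dtype=bool)
    vmask[val_pick] = True
    val = [p for p, m in zip(pool, vmask) if m]
    train = [p for p, m in zip(pool, vmask) if not m]

    params = {m.model_id: m.to_dict() for m in morphologies}
    return SplitManifest(test_ids=test, val_ids=val, train_ids=train, seed=seed, params=params)
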