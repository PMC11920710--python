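"""Canonical ordering of point clouds and 2D grid encoding.

A CNN consuming a point cloud needs a consistent point order.  PCA ordering
aligns each cloud with its principal axes (eigenvectors of the coordinate
covariance) and sorts points by their projection on the leading axis; axis
ordering simply sorts on one raw coordinate.  The ordered features are then
reshaped row-major into a rows x cols grid (consecutive blocks of ``cols``
sorted points become grid rows).

Eigenvector signs are fixed deterministically.  When the caller supplies
references (an inflow direction for the leading axis, a surface-frame normal
for the minor axis — both recoverable from the structured clouds this
package produces), the axes are oriented by nonnegative dot product with
them.  Otherwise rotation-invariant moment conventions apply: the leading
axis points toward the cloud end with the larger internal lateral spread,
then toward nonnegative projection skewness, with the nonnegative
largest-magnitude-component rule as the last resort.  The second axis always
completes a right-handed basis, so the aligned frame carries no residual
reflection freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Ordering", "OrderedGrid", "pca_order", "axis_order", "to_grid", "from_grid"]

_AXES = {"X": 0, "Y": 1, "Z": 2}


class DegenerateCloudError(ValueError):
    """Raised when a cloud has no spatial extent (all points identical)."""


@dataclass
class Ordering:
    """A canonical point order: permutation plus the frame that induced it.

    ``aligned(coords)`` expresses coordinates in the ordering's canonical
    frame (centered, rotated onto the principal axes for PCA; centered only
    for axis orderings).
    """

    permutation: np.ndarray  # (N,) int
    method: str  # "PCA", "X", "Y" or "Z"
    mean: np.ndarray = field(default_factory=lambda: np.zeros(3))
    basis: np.ndarray = field(default_factory=lambda: np.eye(3))  # columns = axes

    def __post_init__(self) -> None:
        perm = np.asarray(self.permutation)
        if not np.array_equal(np.sort(perm), np.arange(len(perm))):
            raise ValueError("permutation is not a bijection on 0..N-1")

    def aligned(self, coords: np.ndarray) -> np.ndarray:
        return (coords - self.mean) @ self.basis

    def inverse(self) -> np.ndarray:
        inv = np.empty_like(self.permutation)
        inv[self.permutation] = np.arange(len(self.permutation))
        return inv


@dataclass
class OrderedGrid:
    """rows x cols x channels tensor encoding of an ordered cloud."""

    tensor: np.ndarray
    channel_names: tuple[str, ...] = ()

    @property
    def rows(self) -> int:
        return self.tensor.shape[0]

    @property
    def cols(self) -> int:
        return self.tensor.shape[1]


def _fix_sign(
    axis: np.ndarray, projections: np.ndarray, perp: np.ndarray | None = None
) -> np.ndarray:
    """Orient one principal axis by a rotation-invariant convention.

    Primary criterion (leading axis only, ``perp`` = perpendicular coordinate
    components): the axis points toward the end of the cloud with the larger
    internal lateral spread, measured as the total perpendicular variance of
    the top versus bottom decile of projections — for branching tubular
    shapes, toward the diverging branches.  Secondary: nonnegative projection
    skewness.  Final fallback for fully symmetric distributions:
    largest-magnitude eigenvector component nonnegative.
    """
    m2 = np.mean(projections**2)
    if perp is not None and m2 > 0:
        lo = perp[projections <= np.quantile(projections, 0.1)]
        hi = perp[projections >= np.quantile(projections, 0.9)]
        v_lo = np.sum(np.var(lo, axis=0)) if len(lo) > 1 else 0.0
        v_hi = np.sum(np.var(hi, axis=0)) if len(hi) > 1 else 0.0
        if abs(v_hi - v_lo) > 1e-8 * (v_hi + v_lo + 1e-30):
            return axis if v_hi > v_lo else -axis
    if m2 > 0:
        g1 = np.mean(projections**3) / m2**1.5
        if abs(g1) > 1e-8:
            return axis if g1 > 0 else -axis
    k = int(np.argmax(np.abs(axis)))
    return axis if axis[k] >= 0 else -axis


def pca_order(
    coords: np.ndarray,
    reference_axis: np.ndarray | None = None,
    reference_normal: np.ndarray | None = None,
) -> Ordering:
    """Order points by projection on the leading covariance eigenvector.

    Ties on the leading projection break lexicographically on the second and
    third principal projections, then on input index (stable sort).

    ``reference_axis`` (e.g. the known inflow direction of a vessel tree)
    orients the leading eigenvector by nonnegative dot product;
    ``reference_normal`` likewise orients the minor axis.  Without
    references, the rotation-invariant moment conventions of
    :func:`_fix_sign` apply.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 3:
        raise DegenerateCloudError(f"need >= 3 points, got {n}")
    mean = coords.mean(axis=0)
    x = coords - mean
    cov = (x.T @ x) / n
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[-1] <= 0:
        raise DegenerateCloudError("rank-0 cloud: all points identical")
    order = np.argsort(evals)[::-1]
    # e1: leading axis, oriented toward growing lateral spread (the branches);
    # e3: smallest-variance axis (the bifurcation-plane normal for planar
    # trees), skewness/component-oriented; e2 completes the right-handed frame
    v1 = evecs[:, order[0]]
    if reference_axis is not None and abs(np.dot(v1, reference_axis)) > 1e-12:
        e1 = v1 if np.dot(v1, reference_axis) >= 0 else -v1
    else:
        proj = x @ v1
        perp = x - proj[:, None] * v1
        e1 = _fix_sign(v1, proj, perp)
    v3 = evecs[:, order[2]]
    if reference_normal is not None and abs(np.dot(v3, reference_normal)) > 1e-12:
        e3 = v3 if np.dot(v3, reference_normal) >= 0 else -v3
    else:
        e3 = _fix_sign(v3, x @ v3)
    e2 = np.cross(e3, e1)
    basis = np.column_stack([e1, e2, e3])
    proj = x @ basis
    # quantized keys: exact symmetric point pairs tie on the leading keys at
    # float precision; quantization (1e-9 length units, far below any point
    # separation) keeps the order permutation-invariant
    k = np.round(proj * 1e9)
    perm = np.lexsort((k[:, 2], k[:, 1], k[:, 0]))
    return Ordering(permutation=perm, method="PCA", mean=mean, basis=basis)


def axis_order(coords: np.ndarray, axis: str) -> Ordering:
    """Ascending sort on one raw coordinate; ties by the others, then index."""
    coords = np.asarray(coords, dtype=float)
    if len(coords) == 0:
        raise DegenerateCloudError("empty cloud")
    a = _AXES[axis.upper()]
    others = [k for k in range(3) if k != a]
    perm = np.lexsort((coords[:, others[1]], coords[:, others[0]], coords[:, a]))
    return Ordering(
        permutation=perm,
        method=axis.upper(),
        mean=coords.mean(axis=0),
        basis=np.eye(3),
    )


def to_grid(
    features: np.ndarray,
    ordering: Ordering,
    rows: int,
    cols: int,
    channel_names: tuple[str, ...] = (),
) -> OrderedGrid:
    """Permute features into canonical order and reshape row-major to a grid."""
    features = np.asarray(features)
    if features.ndim == 1:
        features = features[:, None]
    n, c = features.shape
    if n != rows * cols:
        raise ValueError(f"N={n} != rows*cols={rows * cols}")
    tensor = features[ordering.permutation].reshape(rows, cols, c)
    return OrderedGrid(tensor=tensor, channel_names=channel_names)


def from_grid(grid: OrderedGrid | np.ndarray, ordering: Ordering) -> np.ndarray:
    """Invert :func:`to_grid`: recover features in original cloud order."""
    tensor = grid.tensor if isinstance(grid, OrderedGrid) else np.asarray(grid)
    rows, cols, c = tensor.shape
    flat = tensor.reshape(rows * cols, c)
    out = np.empty_like(flat)
    out[ordering.permutation] = flat
    return out
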