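"""Across-subject parameter-map correlation with TFCE and permutation FWER.

For every voxel inside a mask, the Pearson correlation between
per-subject GLM weights and a scalar covariate (a fitted model
parameter, mean RT, or the congruency RT difference) is Fisher
z-transformed.  The signed z map is enhanced by threshold-free cluster
enhancement (TFCE, E = 0.5, H = 2) and the absolute enhanced value is
compared against the permutation distribution of the image-wide maximum
statistic under covariate shuffling, yielding family-wise error
corrected two-tailed p-values.  The p map is split by the observed sign
into a positive-tail and a negative-tail map, with the complementary
voxels set to p = 1.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "GroupMaps",
    "TFCEResult",
    "voxelwise_fisher_z",
    "tfce",
    "max_stat_permutation",
]

_R_CAP = 1.0 - 1e-12

_STRUCTURES = {6: ndimage.generate_binary_structure(3, 1),
               18: ndimage.generate_binary_structure(3, 2),
               26: ndimage.generate_binary_structure(3, 3)}


@dataclass
class GroupMaps:
    """Per-subject statistic maps plus a covariate and an optional mask."""

    maps: np.ndarray          # (n_subjects, *vol_shape)
    covariate: np.ndarray     # (n_subjects,)
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.maps = np.asarray(self.maps, float)
        self.covariate = np.asarray(self.covariate, float)
        n = self.maps.shape[0]
        if n < 5:
            raise ValueError(f"need >= 5 subjects, got {n}")
        if self.covariate.shape != (n,):
            raise ValueError("covariate length must match the number of maps")
        if np.ptp(self.covariate) == 0:
            raise ValueError("covariate has zero variance")
        if self.mask is None:
            self.mask = np.ones(self.maps.shape[1:], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, bool)
            if self.mask.shape != self.maps.shape[1:]:
                raise ValueError("mask shape must match the map shape")
        if not np.isfinite(self.maps[:, self.mask]).all():
            raise ValueError("maps contain non-finite values inside the mask")

    @property
    def n_subjects(self) -> int:
        return self.maps.shape[0]


@dataclass
class TFCEResult:
    """Signed TFCE map with one-tailed FWER-corrected p maps."""

    tfce_map: np.ndarray
    z_map: np.ndarray
    p_pos: np.ndarray
    p_neg: np.ndarray
    n_permutations: int
    exact: bool = False

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        return (self.p_pos < alpha) | (self.p_neg < alpha)


def _fisher_z_flat(maps_flat: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """Fisher-z Pearson correlations, vectorized over columns.

    Constant columns get z = 0; |r| is capped just below 1 so the
    transform stays finite.
    """
    x = covariate - covariate.mean()
    y = maps_flat - maps_flat.mean(axis=0)
    sx = np.sqrt((x ** 2).sum())
    sy = np.sqrt((y ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (x @ y) / (sx * sy)
    r = np.where(sy > 0, r, 0.0)
    r = np.clip(r, -_R_CAP, _R_CAP)
    return np.arctanh(r)


def voxelwise_fisher_z(maps, covariate, mask=None) -> np.ndarray:
    """Fisher z-transformed Pearson correlation map across subjects.

    Outside-mask voxels are NaN; voxels with a constant map across
    subjects give z = 0 with a warning.
    """
    gm = maps if isinstance(maps, GroupMaps) else GroupMaps(
        np.asarray(maps, float), covariate, mask)
    flat = gm.maps[:, gm.mask]
    const = np.ptp(flat, axis=0) == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} masked voxel(s) are constant "
                      "across subjects; their z is set to 0", RuntimeWarning)
    z = _fisher_z_flat(flat, gm.covariate)
    out = np.full(gm.maps.shape[1:], np.nan)
    out[gm.mask] = z
    return out


def tfce(stat_map, E: float = 0.5, H: float = 2.0, dh: float | None = None,
         connectivity: int = 26) -> np.ndarray:
    """Threshold-free cluster enhancement of a signed statistic map.

    Each voxel accumulates ``extent(h)^E * h^H * dh`` over thresholds
    ``h`` from ``dh`` up to the map maximum, where extent(h) is the size
    of the suprathreshold connected component containing the voxel.
    The positive part and the negated negative part are enhanced
    separately and recombined with sign.  ``dh`` defaults to
    ``max|map| / 100``.
    """
    m = np.nan_to_num(np.asarray(stat_map, float))
    peak = np.abs(m).max()
    if peak == 0:
        return np.zeros_like(m)
    step = peak / 100.0 if dh is None else float(dh)
    struct = _STRUCTURES[connectivity] if m.ndim == 3 else \
        ndimage.generate_binary_structure(m.ndim, m.ndim)
    pos = _tfce_one_sided(np.clip(m, 0, None), E, H, step, struct)
    neg = _tfce_one_sided(np.clip(-m, 0, None), E, H, step, struct)
    return pos - neg


def _tfce_one_sided(part: np.ndarray, E: float, H: float, step: float,
                    struct) -> np.ndarray:
    top = part.max()
    acc = np.zeros_like(part)
    if top == 0 or step <= 0:
        return acc
    # midpoint rule over thresholds (unbiased to O(step^2))
    for h in (np.arange(int(np.ceil(top / step))) + 0.5) * step:
        labels, n = ndimage.label(part >= h, structure=struct)
        if n == 0:
            break
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        acc += (sizes[labels] ** E) * (h ** H) * step
    return acc


def _tfce_stat(maps_flat, covariate, mask, E, H, dh, connectivity):
    """|TFCE(Fisher-z map)| for one covariate labeling."""
    z = _fisher_z_flat(maps_flat, covariate)
    vol = np.zeros(mask.shape)
    vol[mask] = z
    return tfce(vol, E=E, H=H, dh=dh, connectivity=connectivity)


def max_stat_permutation(maps, covariate=None, n_perm: int = 1000,
                         rng=None, mask=None, E: float = 0.5, H: float = 2.0,
                         dh: float | None = None, connectivity: int = 26
                         ) -> TFCEResult:
    """Maximal-statistic permutation FWER test of the TFCE'd correlation map.

    The observed statistic is ``|TFCE(Fisher-z map)|`` per voxel; the
    null distribution is the image-wide maximum of the same statistic
    under random permutation of the covariate.  Voxel p-values use the
    +1-smoothed estimator ``(1 + #{null max >= observed}) / (1 + n_perm)``
    and are split by the observed sign into positive- and negative-tail
    maps (complementary voxels set to 1).  When ``n_perm`` is at least
    the number of distinct covariate orderings the permutations are
    enumerated exactly instead.
    """
    gm = maps if isinstance(maps, GroupMaps) else GroupMaps(
        np.asarray(maps, float), covariate, mask)
    if n_perm < 100:
        raise ValueError("need n_perm >= 100")
    rng = np.random.default_rng(rng)
    flat = gm.maps[:, gm.mask]
    n = gm.n_subjects

    signed = _tfce_stat(flat, gm.covariate, gm.mask, E, H, dh, connectivity)
    observed = np.abs(signed)

    n_total = math.factorial(n)
    exact = n_perm >= n_total
    if exact:
        perms = [np.array(p) for p in
                 itertools.permutations(range(n))]
    else:
        perms = [rng.permutation(n) for _ in range(n_perm)]

    exceed = np.zeros(gm.mask.shape)
    for perm in perms:
        null_map = _tfce_stat(flat, gm.covariate[perm], gm.mask, E, H, dh,
                              connectivity)
        null_max = np.abs(null_map).max()
        exceed += null_max >= observed

    if exact:
        p = exceed / n_total  # identity permutation guarantees p > 0
        n_used = n_total
    else:
        p = (1.0 + exceed) / (1.0 + n_perm)
        n_used = n_perm

    p_pos = np.where((signed > 0) & gm.mask, p, 1.0)
    p_neg = np.where((signed < 0) & gm.mask, p, 1.0)
    z_map = np.full(gm.mask.shape, np.nan)
    z_map[gm.mask] = _fisher_z_flat(flat, gm.covariate)
    return TFCEResult(signed, z_map, p_pos, p_neg, n_used, exact=exact)
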