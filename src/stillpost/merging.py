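"""Reference generation, selection, outlier rejection, merging and CC1/2.

Equivalent observations (same reduced Miller index) are combined by the
sigma-weighted average

    <I_h> = sum_i W_i I_i / sum_i W_i,   W_i = 1/sigma_i^2(I_full),

with sigma(<I_h>) = sqrt(1 / sum_i W_i).  Before merging, an iterative
3-sigma rejection discards outliers within each group.  Data quality is
assessed by CC1/2: per reflection the observations are randomly split into
two halves (reflections with fewer than four observations are excluded),
each half is merged, and CC1/2 is the Pearson correlation between the two
half-set means across reflections.

Symmetry handling (asymmetric-unit reduction, systematic absences, centric
flags, unique-reflection enumeration) is delegated to gemmi.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

from .geometry import UnitCell
from .partiality import predict_reflections

__all__ = [
    "SelectionCriteria",
    "ReferenceSet",
    "MergedDataset",
    "reduce_miller",
    "select_reflections",
    "cell_within_tolerance",
    "reject_outliers",
    "weighted_mean",
    "merge",
    "cc_half",
    "unique_reflection_set",
    "merging_stats",
    "initial_reference",
]

log = logging.getLogger("stillpost")


def _encode_hkl(hkl: np.ndarray) -> np.ndarray:
    """Pack (h, k, l) into a single int64 for vectorized lookups."""
    h = np.atleast_2d(np.asarray(hkl, dtype=np.int64))
    return ((h[:, 0] + 1024) << 22) | ((h[:, 1] + 1024) << 11) | (h[:, 2] + 1024)


def _space_group(name: str | gemmi.SpaceGroup) -> gemmi.SpaceGroup:
    if isinstance(name, gemmi.SpaceGroup):
        return name
    sg = gemmi.find_spacegroup_by_name(name)
    if sg is None:
        raise ValueError(f"unknown space group {name!r}")
    return sg


@dataclass
class SelectionCriteria:
    """Per-observation filters used before refinement and merging.

    Resolution bounds in Angstrom (``None`` = unbounded), a minimum
    signal-to-noise I/sigma(I), a floor on the Ewald-offset correction
    (1/Eoc amplifies noise without bound as Eoc -> 0), and the maximum
    fractional deviation of a frame's refined cell from the target cell
    before the whole frame is excluded from merging.
    """

    d_max: float | None = None
    d_min: float | None = None
    min_i_over_sigma: float = -math.inf
    min_eoc: float = 0.10
    max_cell_deviation: float = 0.05

    def __post_init__(self) -> None:
        if self.d_max is not None and self.d_min is not None and self.d_max <= self.d_min:
            raise ValueError("d_max must exceed d_min")


@dataclass
class ReferenceSet:
    """Merged full intensities keyed by reduced Miller index."""

    miller: np.ndarray  # (m, 3) int
    i_ref: np.ndarray
    sigma: np.ndarray
    n_obs: np.ndarray
    _keys: np.ndarray = field(default=None, repr=False)
    _order: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.miller = np.atleast_2d(np.asarray(self.miller, dtype=int))
        keys = _encode_hkl(self.miller)
        self._order = np.argsort(keys)
        self._keys = keys[self._order]

    def __len__(self) -> int:
        return len(self.i_ref)

    def lookup(self, reduced: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(I_ref values, found mask) for an (n, 3) array of reduced indices."""
        q = _encode_hkl(np.asarray(reduced, dtype=int))
        pos = np.searchsorted(self._keys, q)
        pos = np.minimum(pos, len(self._keys) - 1)
        found = self._keys[pos] == q
        vals = np.full(len(q), np.nan)
        vals[found] = self.i_ref[self._order[pos[found]]]
        return vals, found

    @classmethod
    def from_merged(cls, dataset: "MergedDataset") -> "ReferenceSet":
        t = dataset.table
        return cls(
            miller=t[["h", "k", "l"]].to_numpy(dtype=int),
            i_ref=t["I"].to_numpy(dtype=float),
            sigma=t["sigma"].to_numpy(dtype=float),
            n_obs=t["n_obs"].to_numpy(dtype=int),
        )


@dataclass
class MergedDataset:
    """Final merged intensities plus bookkeeping and shell statistics."""

    table: pd.DataFrame  # columns h, k, l, I, sigma, n_obs, n_rej
    space_group: str
    cell: UnitCell
    d_max: float | None = None
    d_min: float | None = None
    cc_half: float | None = None
    stats: pd.DataFrame | None = None


def reduce_miller(space_group, hkl, anomalous: bool = False) -> np.ndarray:
    """Map Miller indices to the reciprocal-space asymmetric unit.

    Friedel mates are merged unless ``anomalous``; in anomalous mode the
    Friedel-negative observations are returned as the negated ASU index so
    that I+ and I- groups stay separate end-to-end.
    """
    sg = _space_group(space_group)
    ops = sg.operations()
    asu = gemmi.ReciprocalAsu(sg)
    out = np.empty((len(hkl), 3), dtype=int)
    for i, row in enumerate(np.asarray(hkl, dtype=int)):
        new, isym = asu.to_asu([int(row[0]), int(row[1]), int(row[2])], ops)
        if anomalous and isym % 2 == 0:  # even isym: Friedel mate was applied
            out[i] = [-new[0], -new[1], -new[2]]
        else:
            out[i] = new
    return out


def select_reflections(pred, obs, criteria: SelectionCriteria) -> np.ndarray:
    """Boolean mask of observations passing the per-observation criteria."""
    mask = np.isfinite(pred.eoc)
    mask &= pred.eoc >= criteria.min_eoc
    if criteria.min_i_over_sigma != -math.inf:
        mask &= obs.intensity / obs.sigma >= criteria.min_i_over_sigma
    d_spacing = getattr(pred, "d", None)
    if d_spacing is not None:
        if criteria.d_min is not None:
            mask &= d_spacing >= criteria.d_min
        if criteria.d_max is not None:
            mask &= d_spacing <= criteria.d_max
    return mask


def cell_within_tolerance(cell: UnitCell, target: UnitCell, max_fraction: float) -> bool:
    """True if every cell length is within the fractional tolerance of the
    target (angles compared on the same fractional scale)."""
    a = np.array(cell.parameters)
    t = np.array(target.parameters)
    return bool(np.all(np.abs(a - t) <= max_fraction * t))


def reject_outliers(values, cutoff: float = 3.0, max_iter: int = 10) -> np.ndarray:
    """Iterative sigma-clipping keep-mask for one group of full intensities.

    Mean and standard deviation are recomputed from the surviving
    observations each round until stable (or ``max_iter``).  Groups of size
    <= 2 are never clipped (the standard deviation is degenerate).
    """
    values = np.asarray(values, dtype=float)
    keep = np.ones(len(values), dtype=bool)
    if len(values) <= 2:
        return keep
    for _ in range(max_iter):
        sub = values[keep]
        if len(sub) <= 2:
            break
        sd = sub.std(ddof=0)
        if sd == 0:
            break
        new = keep & (np.abs(values - sub.mean()) <= cutoff * sd)
        if new.sum() == keep.sum():
            break
        keep = new
    return keep


def weighted_mean(i, sigma) -> tuple[float, float]:
    """Sigma-weighted mean and its standard error (W_i = 1/sigma_i^2)."""
    w = 1.0 / np.square(np.asarray(sigma, dtype=float))
    sw = w.sum()
    return float((w * np.asarray(i, dtype=float)).sum() / sw), float(math.sqrt(1.0 / sw))


def _group_slices(reduced: np.ndarray):
    """Yield (unique_hkl, index_array) for each distinct reduced index."""
    reduced = np.atleast_2d(np.asarray(reduced, dtype=int))
    keys = _encode_hkl(reduced)
    order = np.argsort(keys, kind="stable")
    sorted_keys = keys[order]
    starts = np.concatenate([[0], np.flatnonzero(np.diff(sorted_keys)) + 1])
    ends = np.concatenate([starts[1:], [len(sorted_keys)]])
    for st, en in zip(starts, ends):
        idx = order[st:en]
        yield reduced[idx[0]], idx


def merge(
    reduced,
    i_full,
    sigma_full,
    space_group: str,
    cell: UnitCell,
    d_max: float | None = None,
    d_min: float | None = None,
    outlier_cutoff: float = 3.0,
) -> MergedDataset:
    """Outlier-reject and sigma-weight-merge observations by reduced index."""
    reduced = np.asarray(reduced, dtype=int)
    i_full = np.asarray(i_full, dtype=float)
    sigma_full = np.asarray(sigma_full, dtype=float)
    rows = []
    for hkl, idx in _group_slices(reduced):
        keep = reject_outliers(i_full[idx], cutoff=outlier_cutoff)
        sel = idx[keep]
        mi, ms = weighted_mean(i_full[sel], sigma_full[sel])
        rows.append((hkl[0], hkl[1], hkl[2], mi, ms, len(sel), int((~keep).sum())))
    table = pd.DataFrame(rows, columns=["h", "k", "l", "I", "sigma", "n_obs", "n_rej"])
    return MergedDataset(table=table, space_group=space_group, cell=cell, d_max=d_max, d_min=d_min)


def cc_half(reduced, i_full, sigma_full, seed: int = 0, min_obs: int = 4) -> float:
    """Half-data-set correlation coefficient.

    Observations of each reflection are shuffled with a seeded RNG and split
    into two halves (odd counts put the extra observation in half 1);
    reflections with fewer than ``min_obs`` observations are excluded.
    Returns NaN when fewer than two reflections are usable.
    """
    rng = np.random.default_rng(seed)
    reduced = np.asarray(reduced, dtype=int)
    i_full = np.asarray(i_full, dtype=float)
    sigma_full = np.asarray(sigma_full, dtype=float)
    a, b = [], []
    for _, idx in _group_slices(reduced):
        if len(idx) < min_obs:
            continue
        perm = rng.permutation(len(idx))
        half = (len(idx) + 1) // 2
        i1 = idx[perm[:half]]
        i2 = idx[perm[half:]]
        a.append(weighted_mean(i_full[i1], sigma_full[i1])[0])
        b.append(weighted_mean(i_full[i2], sigma_full[i2])[0])
    if len(a) < 2:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def unique_reflection_set(
    cell: UnitCell,
    space_group: str,
    d_max: float | None,
    d_min: float,
    anomalous: bool = False,
) -> tuple[np.ndarray, int]:
    """Enumerate the unique reduced Miller indices in a resolution range.

    Bounds are inclusive (d_min <= d <= d_max).  Systematic absences are
    excluded.  In anomalous mode every acentric reflection contributes a
    separate Friedel mate.
    """
    sg = _space_group(space_group)
    arr = gemmi.make_miller_array(cell.to_gemmi(), sg, d_min, d_max or 0.0, unique=True)
    arr = np.asarray(arr, dtype=int)
    if not anomalous:
        return arr, len(arr)
    ops = sg.operations()
    centric = np.array([ops.is_reflection_centric([int(h), int(k), int(l)]) for h, k, l in arr])
    mates = -arr[~centric]
    full = np.vstack([arr, mates])
    return full, len(full)


def _shell_edges(d_max: float, d_min: float, n_shells: int) -> np.ndarray:
    """Equal reciprocal-volume shell edges, returned as d-spacings (desc)."""
    s3 = np.linspace(1.0 / d_max**3, 1.0 / d_min**3, n_shells + 1)
    return s3 ** (-1.0 / 3.0)


def merging_stats(
    merged: MergedDataset,
    n_shells: int = 10,
    reduced_obs: np.ndarray | None = None,
    i_obs: np.ndarray | None = None,
    sigma_obs: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-shell completeness, multiplicity and (optionally) CC1/2.

    Shells have equal reciprocal volume.  Completeness compares measured
    unique reflections against the full enumeration for the same cell,
    space group and resolution range; multiplicity is observations per
    measured unique index.  When the unmerged observations are supplied,
    CC1/2 is computed per shell; empty shells report completeness 0 and
    multiplicity 0.  The last row holds the overall values.
    """
    cell = merged.cell
    table = merged.table
    gcell = cell.to_gemmi()
    d_meas = np.array(
        [gcell.calculate_d([int(h), int(k), int(l)]) for h, k, l in table[["h", "k", "l"]].to_numpy()]
    )
    d_max = merged.d_max or float(d_meas.max())
    d_min = merged.d_min or float(d_meas.min())
    possible, _ = unique_reflection_set(cell, merged.space_group, d_max, d_min, anomalous=False)
    d_poss = np.array([gcell.calculate_d([int(h), int(k), int(l)]) for h, k, l in possible])
    edges = _shell_edges(d_max, d_min, n_shells)

    have_obs = reduced_obs is not None and i_obs is not None and sigma_obs is not None
    if have_obs:
        d_obs = np.array(
            [gcell.calculate_d([int(h), int(k), int(l)]) for h, k, l in np.asarray(reduced_obs)]
        )

    rows = []
    for j in range(n_shells):
        hi, lo = edges[j], edges[j + 1]  # hi = larger d
        in_meas = (d_meas <= hi + 1e-9) & (d_meas >= lo - 1e-9) if j == n_shells - 1 else (
            (d_meas <= hi + 1e-9) & (d_meas > lo)
        )
        in_poss = (d_poss <= hi + 1e-9) & (d_poss >= lo - 1e-9) if j == n_shells - 1 else (
            (d_poss <= hi + 1e-9) & (d_poss > lo)
        )
        n_meas = int(in_meas.sum())
        n_poss = int(in_poss.sum())
        mult = float(table["n_obs"][in_meas].sum() / n_meas) if n_meas else 0.0
        cc = float("nan")
        if have_obs:
            in_obs = (d_obs <= hi + 1e-9) & (d_obs >= lo - 1e-9) if j == n_shells - 1 else (
                (d_obs <= hi + 1e-9) & (d_obs > lo)
            )
            if in_obs.sum():
                cc = cc_half(
                    np.asarray(reduced_obs)[in_obs],
                    np.asarray(i_obs)[in_obs],
                    np.asarray(sigma_obs)[in_obs],
                    seed=seed,
                )
        rows.append((hi, lo, n_poss, n_meas, n_meas / n_poss if n_poss else 0.0, mult, cc))

    n_meas_all = len(table)
    n_poss_all = len(possible)
    cc_all = (
        cc_half(reduced_obs, i_obs, sigma_obs, seed=seed) if have_obs else float("nan")
    )
    rows.append(
        (
            d_max,
            d_min,
            n_poss_all,
            n_meas_all,
            n_meas_all / n_poss_all if n_poss_all else 0.0,
            float(table["n_obs"].sum() / n_meas_all) if n_meas_all else 0.0,
            cc_all,
        )
    )
    return pd.DataFrame(
        rows,
        columns=["d_max", "d_min", "n_possible", "n_measured", "completeness", "multiplicity", "cc_half"],
    )


def initial_reference(
    frames,
    models,
    criteria: SelectionCriteria,
    anomalous: bool = False,
) -> ReferenceSet:
    """Build the starting reference set from unmerged, unscaled partials.

    Per-frame linear scale factors equalize the mean intensity of a selected
    subset (resolution and I/sigma cuts) across frames; observations are
    then Ewald-offset- and volume-corrected with the starting parameters and
    merged with experimental-sigma weighting.
    """
    frame_means = []
    cached = []
    for frame, model in zip(frames, models):
        pred = predict_reflections(frame, model)
        sel = select_reflections(pred, frame.obs, criteria)
        if not sel.any():
            cached.append(None)
            frame_means.append(np.nan)
            continue
        cached.append((pred, sel))
        frame_means.append(float(frame.obs.intensity[sel].mean()))
    frame_means = np.asarray(frame_means)
    usable = np.isfinite(frame_means) & (frame_means > 0)
    if not usable.any():
        raise ValueError("no frame passes the reference-selection criteria")
    target = float(frame_means[usable].mean())

    reduced_all, i_all, s_all = [], [], []
    for frame, entry, mean_i, ok in zip(frames, cached, frame_means, usable):
        if entry is None or not ok:
            continue
        pred, sel = entry
        k = target / mean_i  # linear scale making frame means equal
        i_corr = pred.vc[sel] * k * frame.obs.intensity[sel] / pred.eoc[sel]
        s_corr = pred.vc[sel] * k * frame.obs.sigma[sel] / pred.eoc[sel]
        if frame.reduced is None:
            frame.reduced = reduce_miller(frame.space_group, frame.obs.miller, anomalous)
        reduced_all.append(frame.reduced[sel])
        i_all.append(i_corr)
        s_all.append(s_corr)

    reduced = np.vstack(reduced_all)
    merged = merge(
        reduced,
        np.concatenate(i_all),
        np.concatenate(s_all),
        space_group=frames[0].space_group,
        cell=models[0].cell,
    )
    return ReferenceSet.from_merged(merged)
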