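"""Whole-brain registered point-cloud statistics.

Inputs are registered cell tables from cleared-brain light-sheet imaging:
one row per detected cell with x/y/z in micrometres of atlas space, a
channel label (e.g. cFos, PV, mCherry) and an atlas region acronym, plus a
region ontology (acronym, parent, exclusive volume).

The central operation is distance-threshold double-positive detection: a
query cell (say c-Fos+) counts as double-positive when at least one
reference cell (say PV+) lies within ``radius_um`` (default 16 um, stated
in the expanded/registered tissue space; divide by the ~1.5x clearing
expansion factor for the native-tissue equivalent).  Cerebellar regions
are excluded by default because cell detection is less accurate there.

The spatial search uses uniform grid hashing with cell size equal to the
radius and is exactly equivalent to exhaustive pairwise search.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats

CELL_COLUMNS = ["x_um", "y_um", "z_um", "intensity", "channel", "region"]
OUTSIDE = "OUTSIDE"


@dataclass
class Ontology:
    """Region hierarchy: acronym -> (parent, exclusive volume in mm^3)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"acronym", "parent", "volume_mm3"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"ontology table missing columns {sorted(missing)}")
        if self.table["acronym"].duplicated().any():
            raise ValueError("duplicate acronyms in ontology")
        self._parent = dict(zip(self.table["acronym"], self.table["parent"]))
        self._volume = dict(zip(self.table["acronym"], self.table["volume_mm3"]))
        children = defaultdict(list)
        for acronym, parent in self._parent.items():
            if parent:
                children[parent].append(acronym)
        self._children = dict(children)

    @property
    def acronyms(self) -> list[str]:
        return list(self._parent)

    def subtree(self, acronym: str) -> set[str]:
        """The region and all its descendants."""
        if acronym not in self._parent:
            raise KeyError(f"unknown region {acronym!r}")
        out = {acronym}
        stack = [acronym]
        while stack:
            for child in self._children.get(stack.pop(), ()):
                out.add(child)
                stack.append(child)
        return out

    def subtree_volume(self, acronym: str) -> float:
        return float(sum(self._volume[a] for a in self.subtree(acronym)))


@dataclass
class BrainCellTable:
    """Registered cells of one brain plus its ontology and group label."""

    cells: pd.DataFrame
    brain_id: str
    group: str
    ontology: Ontology

    def __post_init__(self) -> None:
        missing = set(CELL_COLUMNS) - set(self.cells.columns)
        if missing:
            raise ValueError(f"cell table missing columns {sorted(missing)}")
        known = set(self.ontology.acronyms) | {OUTSIDE}
        bad = set(self.cells["region"].unique()) - known
        if bad:
            raise ValueError(f"regions {sorted(bad)} absent from ontology")
        xyz = self.cells[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        if xyz.size and not np.all(np.isfinite(xyz)):
            raise ValueError("non-finite cell coordinates")

    def channel(self, name: str) -> pd.DataFrame:
        return self.cells[self.cells["channel"] == name]


@dataclass(frozen=True)
class ColocParams:
    """Double-positive search parameters (distances in expanded space)."""

    radius_um: float = 16.0
    expansion_factor: float = 1.5
    exclude_regions: tuple[str, ...] = ("CB",)

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("radius must be positive")
        if self.expansion_factor < 1:
            raise ValueError("expansion factor must be >= 1")


def native_radius(params: ColocParams) -> float:
    """Colocalization radius expressed in untreated-tissue micrometres."""
    return params.radius_um / params.expansion_factor


def _excluded_regions(ontology: Ontology, roots: tuple[str, ...]) -> set[str]:
    out: set[str] = set()
    for root in roots:
        if root in ontology._parent:
            out |= ontology.subtree(root)
    return out


def _grid_radius_flags(
    query: np.ndarray, ref: np.ndarray, radius: float
) -> np.ndarray:
    """True for each query point with >= 1 reference point within radius.

    Uniform grid hash with cell size = radius; exact (same set as brute
    force) because all candidates in the 27 neighbouring cells are distance
    checked.
    """
    flags = np.zeros(len(query), dtype=bool)
    if len(query) == 0 or len(ref) == 0:
        return flags
    inv = 1.0 / radius
    ref_keys = np.floor(ref * inv).astype(np.int64)
    buckets: dict[tuple[int, int, int], list[int]] = defaultdict(list)
    for idx, key in enumerate(map(tuple, ref_keys)):
        buckets[key].append(idx)
    buckets = {k: np.asarray(v, dtype=np.intp) for k, v in buckets.items()}
    r2 = radius * radius
    q_keys = np.floor(query * inv).astype(np.int64)
    offsets = [
        (dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    ]
    for i, (kx, ky, kz) in enumerate(q_keys):
        p = query[i]
        hit = False
        for dx, dy, dz in offsets:
            idxs = buckets.get((kx + dx, ky + dy, kz + dz))
            if idxs is None:
                continue
            d = ref[idxs] - p
            if np.any(np.einsum("ij,ij->i", d, d) <= r2):
                hit = True
                break
        flags[i] = hit
    return flags


def double_positive(
    table: BrainCellTable,
    query_channel: str,
    ref_channel: str,
    params: ColocParams = ColocParams(),
) -> pd.DataFrame:
    """Query cells (excluded regions dropped) with a ``double_positive`` flag.

    A query cell is flagged iff at least one reference cell lies within
    ``params.radius_um`` (Euclidean, expanded space); it counts once no
    matter how many neighbours it has.  An empty reference channel yields
    zero flags, which is a valid result.
    """
    excluded = _excluded_regions(table.ontology, params.exclude_regions)
    q = table.channel(query_channel)
    r = table.channel(ref_channel)
    q = q[~q["region"].isin(excluded)].copy()
    r = r[~r["region"].isin(excluded)]
    flags = _grid_radius_flags(
        q[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
        r[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
        params.radius_um,
    )
    q["double_positive"] = flags
    return q


def region_counts(
    table: BrainCellTable, channel: str, regions: list[str] | None = None
) -> pd.Series:
    """Cell counts per region subtree (child counts roll up into parents)."""
    regions = regions if regions is not None else table.ontology.acronyms
    cells = table.channel(channel)
    leaf_counts = cells["region"].value_counts()
    out = {}
    for region in regions:
        members = table.ontology.subtree(region)
        out[region] = int(leaf_counts.reindex(list(members)).fillna(0).sum())
    return pd.Series(out, name=f"{channel}_count")


def region_density(
    table: BrainCellTable, channel: str, regions: list[str] | None = None
) -> pd.Series:
    """Cells per mm^3 per region subtree (subtree count / subtree volume)."""
    counts = region_counts(table, channel, regions)
    out = {}
    for region, count in counts.items():
        vol = table.ontology.subtree_volume(region)
        if vol <= 0:
            raise ValueError(f"region {region!r} has nonpositive subtree volume")
        out[region] = count / vol
    return pd.Series(out, name=f"{channel}_per_mm3")


def normalized_group_density(
    test_brains: list[BrainCellTable],
    control_brains: list[BrainCellTable],
    channel: str,
    regions: list[str] | None = None,
) -> pd.DataFrame:
    """Each test brain's region density divided by the control-group mean.

    Rows are regions, columns are test brain ids; regions whose control
    mean is zero get NaN.
    """
    if not control_brains:
        raise ValueError("at least one control brain required")
    control = pd.concat(
        [region_density(b, channel, regions) for b in control_brains], axis=1
    ).mean(axis=1)
    out = {}
    for brain in test_brains:
        dens = region_density(brain, channel, regions)
        ratio = dens / control.replace(0.0, np.nan)
        out[brain.brain_id] = ratio
    return pd.DataFrame(out)


def double_positive_rates(
    table: BrainCellTable,
    query_channel: str,
    ref_channel: str,
    params: ColocParams = ColocParams(),
    regions: list[str] | None = None,
) -> pd.DataFrame:
    """Double-positive rates |A^B|/|A| and |A^B|/|B| per region and overall.

    Counts pool cells across each region subtree before dividing;
    denominators are taken after region exclusion.  Empty denominators
    yield NaN.  The "overall" row pools everything outside the excluded
    regions.
    """
    flagged = double_positive(table, query_channel, ref_channel, params)
    excluded = _excluded_regions(table.ontology, params.exclude_regions)
    ref = table.channel(ref_channel)
    ref = ref[~ref["region"].isin(excluded)]
    region_list = regions if regions is not None else table.ontology.acronyms
    rows = {}
    for region in [*region_list, "overall"]:
        if region == "overall":
            in_region_q = np.ones(len(flagged), dtype=bool)
            in_region_r = np.ones(len(ref), dtype=bool)
        else:
            members = table.ontology.subtree(region)
            in_region_q = flagged["region"].isin(members).to_numpy()
            in_region_r = ref["region"].isin(members).to_numpy()
        n_q = int(in_region_q.sum())
        n_r = int(in_region_r.sum())
        n_dp = int(flagged.loc[in_region_q, "double_positive"].sum())
        rows[region] = {
            "n_double_positive": n_dp,
            "n_query": n_q,
            "n_ref": n_r,
            "rate_in_query": n_dp / n_q if n_q else float("nan"),
            "rate_in_ref": n_dp / n_r if n_r else float("nan"),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def ppv(
    table: BrainCellTable,
    labeled_channel: str,
    marker_channel: str,
    params: ColocParams = ColocParams(),
) -> float:
    """Positive predictive value of a label for a marker.

    Fraction of labeled cells (e.g. mCherry+) with a marker cell (e.g.
    PV+) within the colocalization radius; NaN when no labeled cells
    remain after exclusion.
    """
    rates = double_positive_rates(table, labeled_channel, marker_channel, params, regions=[])
    return float(rates.loc["overall", "rate_in_query"])


def region_heatmap(
    group_a: list[BrainCellTable],
    group_b: list[BrainCellTable],
    channel: str,
    regions: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-region ratio of group means with a Welch significance mask.

    ``ratio`` is mean(B)/mean(A) of per-brain subtree counts; ``p_value``
    is a per-region two-sided Welch t-test across brains (NaN, with a
    refusal to test, when a group has fewer than two brains).
    ``significant`` masks regions at ``alpha`` (raw P, no multiplicity
    correction, matching the heat-map display convention).
    """
    if not group_a or not group_b:
        raise ValueError("both groups need at least one brain")
    regions = regions if regions is not None else group_a[0].ontology.acronyms
    counts_a = pd.concat([region_counts(b, channel, regions) for b in group_a], axis=1)
    counts_b = pd.concat([region_counts(b, channel, regions) for b in group_b], axis=1)
    mean_a = counts_a.mean(axis=1)
    mean_b = counts_b.mean(axis=1)
    ratio = mean_b / mean_a.replace(0.0, np.nan)
    can_test = len(group_a) >= 2 and len(group_b) >= 2
    pvals = {}
    for region in regions:
        a = counts_a.loc[region].to_numpy(dtype=float)
        b = counts_b.loc[region].to_numpy(dtype=float)
        if not can_test or (np.ptp(a) == 0 and np.ptp(b) == 0):
            pvals[region] = float("nan")
            continue
        pvals[region] = float(spstats.ttest_ind(b, a, equal_var=False).pvalue)
    out = pd.DataFrame({"ratio": ratio, "p_value": pd.Series(pvals)})
    out["significant"] = out["p_value"] < alpha
    return out


@dataclass
class VoxelTestResult:
    """Voxel-wise group comparison on a regular grid.

    ``ratio``, ``p_value`` and ``direction`` (+1 increase in B, -1
    decrease, 0 untested) are arrays of shape ``shape``; ``valid`` marks
    voxels that passed the validity rules.  ``origin``/``spacing`` are in
    micrometres.
    """

    ratio: np.ndarray
    p_value: np.ndarray
    direction: np.ndarray
    valid: np.ndarray
    origin: np.ndarray
    spacing: float

    def positive_rate(self, alpha: float = 0.05) -> float:
        """Fraction of valid voxels with p below alpha."""
        if not np.any(self.valid):
            return float("nan")
        return float(np.mean(self.p_value[self.valid] < alpha))


def _voxel_counts(
    brains: list[BrainCellTable], channel: str, edges: list[np.ndarray]
) -> np.ndarray:
    out = []
    for brain in brains:
        xyz = brain.channel(channel)[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        counts, _ = np.histogramdd(xyz, bins=edges)
        out.append(counts)
    return np.stack(out)


def voxelwise_test(
    group_a: list[BrainCellTable],
    group_b: list[BrainCellTable],
    channel: str,
    voxel_um: float = 100.0,
    alpha: float = 0.05,
    fdr: bool = False,
) -> VoxelTestResult:
    """Welch two-sided t-test of per-voxel cell counts between groups.

    Cells are binned into cubic voxels of ``voxel_um``; each voxel's
    per-brain counts are compared across groups.  A voxel is valid when
    both groups have >= 2 brains, at least one group has nonzero variance,
    and not every count is zero; invalid voxels are masked, not errors.
    Raw p-values are reported by default (the heat-map display
    convention); ``fdr=True`` replaces them with Benjamini-Hochberg
    adjusted values over the valid voxels.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("voxelwise test needs >= 2 brains per group")
    all_xyz = np.vstack(
        [
            b.channel(channel)[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
            for b in [*group_a, *group_b]
        ]
    )
    if all_xyz.size == 0:
        raise ValueError("no cells in the requested channel")
    lo = all_xyz.min(axis=0)
    hi = all_xyz.max(axis=0)
    edges = [
        np.arange(lo[d], hi[d] + voxel_um, voxel_um) for d in range(3)
    ]
    edges = [e if e.size >= 2 else np.array([lo[d], lo[d] + voxel_um]) for d, e in enumerate(edges)]
    counts_a = _voxel_counts(group_a, channel, edges)
    counts_b = _voxel_counts(group_b, channel, edges)
    mean_a = counts_a.mean(axis=0)
    mean_b = counts_b.mean(axis=0)
    var_a = counts_a.var(axis=0, ddof=1)
    var_b = counts_b.var(axis=0, ddof=1)
    valid = ((var_a > 0) | (var_b > 0)) & ((mean_a > 0) | (mean_b > 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        result = spstats.ttest_ind(counts_b, counts_a, axis=0, equal_var=False)
        pvals = np.where(valid, result.pvalue, np.nan)
        ratio = np.where(mean_a > 0, mean_b / np.where(mean_a > 0, mean_a, 1.0), np.nan)
    if fdr and np.any(valid):
        from statsmodels.stats.multitest import multipletests

        adjusted = multipletests(pvals[valid], method="fdr_bh")[1]
        pvals = pvals.copy()
        pvals[valid] = adjusted
    direction = np.zeros(mean_a.shape, dtype=int)
    sig = valid & (pvals < alpha)
    direction[sig & (mean_b > mean_a)] = 1
    direction[sig & (mean_b < mean_a)] = -1
    return VoxelTestResult(
        ratio=ratio,
        p_value=pvals,
        direction=direction,
        valid=valid,
        origin=lo,
        spacing=voxel_um,
    )
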