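"""3D wing morphometrics: point-cloud alignment, spanwise slicing, and the
four cross-sectional shape traits (camber, chord, thickness, area).

A scanned wing is a vertex cloud.  The pipeline is:

1. :func:`align_pointcloud` — rigid alignment to the wing convention
   (X base-to-tip along the span, Y along the chord, Z through the
   thickness) by principal axes, with sign disambiguation from chord taper
   and the camber arch.
2. :func:`slice_wing` — chordwise slices of width 1/25 of the wrist-to-tip
   distance: 25 handwing (HW) bins from wrist to tip and as many armwing
   (AW) bins as fit from wrist to base, the proximal bin adjacent to the
   joint labelled WRIST.
3. :func:`measure_slice` — per-slice traits: chord = Y_max - Y_min;
   camber = (Z_max - Z_min)/chord; maximum cross-sectional thickness (XST)
   as the largest upper-to-lower surface distance over matched chordwise
   stations; cross-sectional area (XSA) as the area of the closed perimeter
   around the slice's Y/Z projection.
4. :func:`scale_by_mass` — isometric body-mass scaling (linear traits by
   Mb^(1/3), areas by Mb^(2/3); camber dimensionless).
5. :func:`summarize_species` / :func:`standardize_profiles` — species
   medians on a common 35-slice (10 AW + 25 HW, wrist excluded) index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WingScan",
    "SliceTraits",
    "TraitProfile",
    "align_pointcloud",
    "slice_wing",
    "measure_slice",
    "scale_by_mass",
    "unscale_by_mass",
    "measure_wing",
    "summarize_species",
    "standardize_profiles",
    "TRAITS",
]

TRAITS = ("camber", "chord", "xst", "xsa")


@dataclass
class WingScan:
    """One specimen's aligned 3D point cloud plus metadata."""

    points: np.ndarray          # (N, 3) coordinates, mm
    species_id: str
    body_mass: float            # grams
    wrist_x: float              # spanwise coordinate of the wrist joint, mm
    specimen_id: str = ""
    side: str = ""

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array")
        if self.points.shape[0] < 3:
            raise ValueError("need at least 3 points")
        if self.body_mass <= 0:
            raise ValueError("body_mass must be positive")
        x = self.points[:, 0]
        if not (x.min() <= self.wrist_x <= x.max()):
            raise ValueError("wrist_x outside the aligned spanwise range")

    @property
    def wing_length(self) -> float:
        """r = X_max - X_min (wingspan = 2 r)."""
        x = self.points[:, 0]
        return float(x.max() - x.min())


@dataclass
class SliceTraits:
    """Four shape traits of one chordwise slice."""

    slice_index: int            # relative to wrist: +1..+25 HW, -1 WRIST, -2.. AW
    region: str                 # "AW" | "WRIST" | "HW"
    camber: float
    chord: float
    xst: float
    xsa: float
    scaled: bool = False
    n_points: int = 0


@dataclass
class TraitProfile:
    """Species × slice matrix of one trait over the standardized slices."""

    trait: str
    values: pd.DataFrame        # index = species, columns = slice labels
    regions: list[str] = field(default_factory=list)   # per column
    scaled: bool = True
    transform: str = "raw"

    def __post_init__(self):
        if len(self.regions) != self.values.shape[1]:
            raise ValueError("one region label per column required")

    @property
    def species_ids(self):
        return list(self.values.index)


def _proper_rotation(evecs: np.ndarray) -> np.ndarray:
    if np.linalg.det(evecs) < 0:
        evecs = evecs.copy()
        evecs[:, 2] *= -1
    return evecs


def align_pointcloud(points: np.ndarray, return_transform: bool = False):
    """Rigidly align a wing point cloud to the spanwise convention.

    Principal axes of the spatial covariance map to (X, Y, Z) in decreasing
    variance order; signs are disambiguated so that (a) the wing tip — the
    half with the smaller mean chord — lies at +X, and (b) the camber arch
    opens downward in Z (mid-chord surface above the chord-edge surface).
    The centroid is moved to the origin.  Rigid transform only (rotation +
    translation, no scaling).

    Returns the aligned cloud, plus ``(R, centroid)`` with
    ``aligned = (points - centroid) @ R.T`` if ``return_transform``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise ValueError("points must be an (N>=3, 3) array")
    centroid = pts.mean(axis=0)
    X = pts - centroid
    cov = X.T @ X / len(X)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[1] <= 1e-12 * max(evals[0], 1.0):
        raise ValueError("degenerate point cloud: points are collinear")
    R = _proper_rotation(evecs).T       # rows = new axes
    A = X @ R.T

    # (a) tip (+X) has the smaller chordwise spread
    tip = A[:, 0] > 0
    if tip.sum() >= 2 and (~tip).sum() >= 2:
        if np.std(A[tip, 1]) > np.std(A[~tip, 1]):
            flip = np.diag([-1.0, -1.0, 1.0])   # 180 deg about Z, stays proper
            R = flip @ R
            A = X @ R.T
    # (b) camber arch opens downward: mid-chord Z above chord-edge Z
    y = A[:, 1]
    yc = np.abs(y - y.mean())
    inner = yc <= np.quantile(yc, 0.3)
    outer = yc >= np.quantile(yc, 0.7)
    if inner.any() and outer.any():
        if A[inner, 2].mean() < A[outer, 2].mean():
            flip = np.diag([1.0, -1.0, -1.0])   # 180 deg about X
            R = flip @ R
            A = X @ R.T
    if return_transform:
        return A, R, centroid
    return A


@dataclass
class WingSlice:
    slice_index: int
    region: str
    x_lo: float
    x_hi: float
    points: np.ndarray          # (m, 3)


def slice_wing(scan: WingScan, n_hw: int = 25, wrist_window: int = 1,
               min_points: int = 10) -> list[WingSlice]:
    """Partition an aligned scan into chordwise slices of width
    w = (X_max - wrist_x)/n_hw.

    Half-open bins [x, x+w) tile from the wrist toward the tip (``n_hw`` HW
    slices, indices +1..+n_hw; the tip point itself is kept in the last bin)
    and from the wrist toward the base (indices -1, -2, ...; as many full
    bins as fit).  The ``wrist_window`` proximal bins adjacent to the joint
    are labelled WRIST (default one), the rest AW.  Bins with fewer than
    ``min_points`` points are flagged with a warning and carry their (small)
    point sets for the caller to mark missing.
    """
    pts = scan.points
    x = pts[:, 0]
    x_max = float(x.max())
    x_min = float(x.min())
    if scan.wrist_x >= x_max:
        raise ValueError("wrist_x must lie proximal to the wing tip (wrist_x < X_max)")
    w = (x_max - scan.wrist_x) / n_hw
    slices: list[WingSlice] = []
    n_aw = int(np.floor((scan.wrist_x - x_min) / w))
    for k in range(n_aw, 0, -1):        # base -> wrist
        lo = scan.wrist_x - k * w
        hi = lo + w
        sel = (x >= lo) & (x < hi)
        region = "WRIST" if k <= wrist_window else "AW"
        slices.append(WingSlice(slice_index=-k, region=region, x_lo=lo, x_hi=hi,
                                points=pts[sel]))
    for k in range(n_hw):               # wrist -> tip
        lo = scan.wrist_x + k * w
        hi = lo + w
        sel = (x >= lo) & (x < hi)
        if k == n_hw - 1:
            sel |= x == x_max
        slices.append(WingSlice(slice_index=k + 1, region="HW", x_lo=lo, x_hi=hi,
                                points=pts[sel]))
    for s in slices:
        if s.region == "HW" and len(s.points) < min_points:
            warnings.warn(f"HW slice {s.slice_index} has only {len(s.points)} points")
    return slices


_SHELL_GAP_FRAC = 0.35   # bimodality threshold: surface gap / station extent


def _station_envelopes(yz: np.ndarray, n_stations: int = 100):
    """Per-station upper/lower surface positions across the chord.

    Slice points are binned into chordwise stations.  A station whose z
    values split into two clusters separated by a dominant gap is treated
    as a thin shell (upper and lower wing surface): the surface positions
    are the cluster means, which cancels the spread induced by spanwise
    taper and camber sweep inside the slice.  Stations without such a gap
    (solid sections, surface folds, sparse stations) fall back to the raw
    z extremes.

    Returns (y_centers, z_upper, z_lower) for stations containing points.
    """
    y, z = yz[:, 0], yz[:, 1]
    # keep ~8+ points per station so surface detection stays reliable
    n_stations = int(np.clip(len(z) // 8, 10, n_stations))
    edges = np.linspace(y.min(), y.max(), n_stations + 1)
    idx = np.clip(np.searchsorted(edges, y, side="right") - 1, 0, n_stations - 1)
    yc, zu, zl = [], [], []
    for s in range(n_stations):
        sel = idx == s
        k = int(sel.sum())
        if k == 0:
            continue
        zs = np.sort(z[sel])
        up, lo = float(zs[-1]), float(zs[0])
        shell = False
        if k >= 4 and up > lo:
            gaps = np.diff(zs)
            g = int(np.argmax(gaps))
            if gaps[g] > _SHELL_GAP_FRAC * (up - lo) and 0 < g + 1 < k:
                shell = True
                lo = float(zs[: g + 1].mean())
                up = float(zs[g + 1:].mean())
        if not shell and k >= 8 and up > lo:
            # filled section: debias the sample range (uniform-range MVUE)
            mid = 0.5 * (up + lo)
            half = 0.5 * (up - lo) * (k + 1) / (k - 1)
            up, lo = mid + half, mid - half
        yc.append(0.5 * (edges[s] + edges[s + 1]))
        zu.append(up)
        zl.append(lo)
    return np.asarray(yc), np.asarray(zu), np.asarray(zl)


def _repair_dropouts(yc: np.ndarray, ext: np.ndarray) -> np.ndarray:
    """Interpolate over stations that sampled only one surface.

    A station whose extent collapses far below both neighbours caught
    points from a single surface by chance; its extent is replaced by
    interpolation from the surrounding stations.
    """
    n = ext.size
    if n < 3:
        return ext
    bad = np.zeros(n, dtype=bool)
    for i in range(n):
        nb = [ext[j] for j in (i - 1, i + 1) if 0 <= j < n and ext[j] > 0]
        if nb and ext[i] < 0.5 * min(nb):
            bad[i] = True
    if bad.all() or not bad.any():
        return ext
    out = ext.copy()
    out[bad] = np.interp(yc[bad], yc[~bad], ext[~bad])
    return out


def _smooth(v: np.ndarray, window: int) -> np.ndarray:
    if v.size < window or window < 2:
        return v
    k = np.ones(window)
    return np.convolve(v, k, "same") / np.convolve(np.ones_like(v), k, "same")


def _xst_stations(yz: np.ndarray, n_stations: int = 100, window: int = 15) -> float:
    """Maximum upper-to-lower surface distance over chordwise stations.

    The extent profile is dropout-repaired and smoothed over neighbouring
    stations before the maximum is taken, suppressing the upward bias of a
    max over per-station sampling noise.
    """
    yc, zu, zl = _station_envelopes(yz, n_stations)
    if yc.size == 0:
        return 0.0
    ext = _repair_dropouts(yc, zu - zl)
    return float(_smooth(ext, window).max())


def _xsa_stations(yz: np.ndarray, n_stations: int = 100) -> float:
    """Section area between the station surface envelopes (trapezoid),
    extended to the full sampled chord."""
    yc, zu, zl = _station_envelopes(yz, n_stations)
    if yc.size < 2:
        return 0.0
    ext = _repair_dropouts(yc, zu - zl)
    y0, y1 = yz[:, 0].min(), yz[:, 0].max()
    ys = np.concatenate([[y0], yc, [y1]])
    es = np.concatenate([[ext[0]], ext, [ext[-1]]])
    return float(np.trapezoid(es, ys))


def _xsa_hull(yz: np.ndarray, ratio: float = 0.05) -> float:
    """Section area from a shapely concave hull of the Y/Z projection."""
    from shapely import MultiPoint, concave_hull

    hull = concave_hull(MultiPoint(yz), ratio=ratio)
    return float(hull.area)


def measure_slice(points: np.ndarray, slice_index: int = 0, region: str = "HW",
                  n_stations: int = 100, xst_method: str = "stations",
                  xsa_method: str = "stations") -> SliceTraits:
    """Measure the four shape traits from one slice's points (raw units).

    chord = Y_max - Y_min; camber = (Z_max - Z_min)/chord from slice-global
    extremes; XST is the greatest upper-to-lower surface distance
    (``xst_method="stations"``: per chordwise station after binning Y into
    ``n_stations`` stations; ``"global"``: Z_max - Z_min); XSA is the area
    of the closed perimeter around the Y/Z projection
    (``xsa_method="stations"`` or ``"hull"``).
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 10:
        raise ValueError(f"slice needs >= 10 points, got {pts.shape[0]}")
    yz = pts[:, 1:3] if pts.shape[1] == 3 else pts
    y, z = yz[:, 0], yz[:, 1]
    chord = float(y.max() - y.min())
    if chord == 0:
        raise ValueError("zero chord: camber undefined")
    z_extent = float(z.max() - z.min())
    camber = z_extent / chord
    if xst_method == "global":
        xst = z_extent
    else:
        xst = _xst_stations(yz, n_stations)
    if xsa_method == "hull":
        xsa = _xsa_hull(yz)
    else:
        xsa = _xsa_stations(yz, n_stations)
    return SliceTraits(slice_index=slice_index, region=region, camber=camber,
                       chord=chord, xst=xst, xsa=xsa, scaled=False,
                       n_points=pts.shape[0])


def scale_by_mass(traits: SliceTraits, body_mass: float) -> SliceTraits:
    """Isometric body-mass scaling: linear traits / Mb^(1/3), areas /
    Mb^(2/3); camber unchanged."""
    if body_mass <= 0:
        raise ValueError("body_mass must be positive")
    if traits.scaled:
        raise ValueError("traits already scaled")
    lin = body_mass ** (1.0 / 3.0)
    return SliceTraits(slice_index=traits.slice_index, region=traits.region,
                       camber=traits.camber, chord=traits.chord / lin,
                       xst=traits.xst / lin, xsa=traits.xsa / lin ** 2,
                       scaled=True, n_points=traits.n_points)


def unscale_by_mass(traits: SliceTraits, body_mass: float) -> SliceTraits:
    """Inverse of :func:`scale_by_mass` (round-trips exactly)."""
    if body_mass <= 0:
        raise ValueError("body_mass must be positive")
    if not traits.scaled:
        raise ValueError("traits are not scaled")
    lin = body_mass ** (1.0 / 3.0)
    return SliceTraits(slice_index=traits.slice_index, region=traits.region,
                       camber=traits.camber, chord=traits.chord * lin,
                       xst=traits.xst * lin, xsa=traits.xsa * lin ** 2,
                       scaled=False, n_points=traits.n_points)


def measure_wing(scan: WingScan, n_hw: int = 25, scale: bool = True,
                 min_points: int = 10, **measure_kw) -> pd.DataFrame:
    """Slice an aligned scan and measure all slices.

    Returns a tidy DataFrame with one row per slice (specimen, species,
    slice_index, region, camber, chord, xst, xsa); slices with too few
    points yield NaN traits.
    """
    rows = []
    for s in slice_wing(scan, n_hw=n_hw, min_points=min_points):
        if len(s.points) < min_points:
            t = SliceTraits(slice_index=s.slice_index, region=s.region,
                            camber=np.nan, chord=np.nan, xst=np.nan, xsa=np.nan,
                            scaled=scale, n_points=len(s.points))
        else:
            t = measure_slice(s.points, slice_index=s.slice_index,
                              region=s.region, **measure_kw)
            if scale:
                t = scale_by_mass(t, scan.body_mass)
        rows.append({"specimen": scan.specimen_id, "species": scan.species_id,
                     "slice_index": t.slice_index, "region": t.region,
                     "camber": t.camber, "chord": t.chord, "xst": t.xst,
                     "xsa": t.xsa, "n_points": t.n_points})
    return pd.DataFrame(rows)


def summarize_species(slice_tables: pd.DataFrame) -> pd.DataFrame:
    """Species medians per slice per trait over specimens.

    Input: concatenated :func:`measure_wing` tables.  Species with zero
    specimens never appear; missing slices propagate as NaN.  Returns a
    DataFrame indexed by (species, slice_index) with region and the four
    trait medians plus specimen counts.
    """
    if slice_tables.empty:
        raise ValueError("no specimen tables supplied")
    g = slice_tables.groupby(["species", "slice_index"], sort=True)
    med = g[list(TRAITS)].median()
    med["region"] = g["region"].first()
    med["n_specimens"] = g["specimen"].nunique()
    return med


def standardize_profiles(species_table: pd.DataFrame, n_aw: int = 10,
                         n_hw: int = 25, include_wrist: bool = False,
                         log10: bool = False) -> dict[str, TraitProfile]:
    """Build analysis-ready TraitProfiles on the common slice index.

    Keeps the ``n_aw`` armwing slices nearest the wrist (relative indices
    -(n_aw+1)..-2), the wrist bin (-1) if ``include_wrist``, and the
    ``n_hw`` handwing slices (+1..+n_hw), ordered base to tip.  Species
    missing any required armwing slice are excluded with a warning.  The
    optional log10 transform serves the modularity analysis (mitigates the
    bias from differing region means).

    Returns {trait: TraitProfile} with 35 columns (36 with the wrist).
    """
    wanted = list(range(-(n_aw + 1), -1))            # AW, base -> wrist
    regions = ["AW"] * n_aw
    if include_wrist:
        wanted.append(-1)
        regions.append("WRIST")
    wanted += list(range(1, n_hw + 1))               # HW, wrist -> tip
    regions += ["HW"] * n_hw
    labels = [f"s{i + 1:02d}" for i in range(len(wanted))]

    profiles: dict[str, TraitProfile] = {}
    wide = species_table.reset_index()
    for trait in TRAITS:
        mat = wide.pivot(index="species", columns="slice_index", values=trait)
        missing_cols = [i for i in wanted if i not in mat.columns]
        if missing_cols:
            mat = mat.reindex(columns=list(mat.columns) + missing_cols)
        sub = mat[wanted]
        ok = sub.notna().all(axis=1)
        dropped = sorted(sub.index[~ok])
        if dropped:
            warnings.warn(f"{trait}: excluded species with incomplete slices: {dropped}")
        vals = sub.loc[ok].copy()
        vals.columns = labels
        transform = "raw"
        if log10:
            if (vals.to_numpy() <= 0).any():
                raise ValueError("log10 transform requires positive trait values")
            vals = np.log10(vals)
            transform = "log10"
        profiles[trait] = TraitProfile(trait=trait, values=vals,
                                       regions=list(regions), transform=transform)
    return profiles
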