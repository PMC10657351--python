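"""Readers and writers for the plain-text formats the pipeline consumes:
point clouds (OBJ/PLY vertex sets, XYZ lists), trait tables (TSV), study
manifests, clade files, and result tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .morphometry import TRAITS, TraitProfile

__all__ = [
    "read_pointcloud",
    "write_obj_points",
    "write_trait_table",
    "read_trait_table",
    "write_trait_tables_combined",
    "read_manifest",
    "read_clades",
    "read_mass_table",
    "load_study_tables",
]


def read_pointcloud(path: str | Path) -> np.ndarray:
    """Vertex set of an OBJ/PLY mesh (faces/normals ignored) or an XYZ list."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"point cloud file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".obj", ".ply"):
        import trimesh

        mesh = trimesh.load(str(path), process=False)
        if hasattr(mesh, "vertices"):
            return np.asarray(mesh.vertices, dtype=float)
        raise ValueError(f"no vertices found in {path}")
    if suffix in (".xyz", ".txt", ".csv"):
        delim = "," if suffix == ".csv" else None
        pts = np.loadtxt(path, delimiter=delim)
        if pts.ndim != 2 or pts.shape[1] < 3:
            raise ValueError(f"{path}: expected columns x y z")
        return pts[:, :3].astype(float)
    raise ValueError(f"unsupported point-cloud format: {suffix}")


def write_obj_points(path: str | Path, points: np.ndarray) -> None:
    """Write bare vertices as a minimal OBJ file."""
    with open(path, "w") as fh:
        for x, y, z in np.asarray(points, dtype=float):
            fh.write(f"v {x:.6f} {y:.6f} {z:.6f}\n")


def write_trait_table(profile: TraitProfile, path: str | Path) -> None:
    """Wide TSV: species rows, slice columns, with a leading region row."""
    df = profile.values.copy()
    header = pd.DataFrame([profile.regions], index=["#region"], columns=df.columns)
    pd.concat([header, df]).rename_axis("species").to_csv(path, sep="\t")


def read_trait_table(path: str | Path, trait: str = "") -> TraitProfile:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "#region" in df.index:
        regions = list(df.loc["#region"])
        df = df.drop(index="#region").astype(float)
    else:  # fall back to the standard 10 AW + 25 HW layout
        df = df.astype(float)
        n = df.shape[1]
        n_aw = 10 if n in (35, 36) else max(n - 25, 0)
        regions = ["AW"] * n_aw + ["HW"] * (n - n_aw)
    if not trait:
        trait = Path(path).stem.replace("traits_", "")
    return TraitProfile(trait=trait, values=df, regions=regions)


def write_trait_tables_combined(profiles: dict[str, TraitProfile],
                                path: str | Path) -> None:
    """Single wide TSV with columns <trait>_s01.. for all traits, plus a
    long-format companion CSV next to it."""
    parts = []
    long_rows = []
    for trait in TRAITS:
        if trait not in profiles:
            continue
        prof = profiles[trait]
        renamed = prof.values.add_prefix(f"{trait}_")
        parts.append(renamed)
        for sp, row in prof.values.iterrows():
            for col, reg in zip(prof.values.columns, prof.regions):
                long_rows.append({"species": sp, "trait": trait, "slice": col,
                                  "region": reg, "value": row[col]})
    pd.concat(parts, axis=1).rename_axis("species").to_csv(path, sep="\t")
    pd.DataFrame(long_rows).to_csv(Path(path).with_suffix(".long.csv"), index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Specimen manifest TSV: specimen, species, mass_g, wrist_x, file."""
    df = pd.read_csv(path, sep="\t")
    required = {"specimen", "species", "mass_g", "wrist_x", "file"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def read_clades(path: str | Path) -> dict[str, list[str]]:
    """Two-column TSV (species, clade) -> {clade: [species...]}."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    out: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row[cols[1]]), []).append(str(row[cols[0]]))
    return out


def read_mass_table(path: str | Path) -> dict[str, float]:
    """Species-mean body-mass fallback table (two columns: species, mass_g)."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = list(df.columns)
    return {str(r[cols[0]]): float(r[cols[1]]) for _, r in df.iterrows()}


def load_study_tables(data_dir: str | Path):
    """Load a deposited study directory: per-trait wide TSVs
    (traits_<trait>.tsv) plus tree.nwk, and optionally clades.tsv.

    Returns (profiles, tree, clades_or_None).
    """
    from .phylo import Phylogeny

    data_dir = Path(data_dir)
    if not data_dir.is_dir():
        raise FileNotFoundError(f"study directory not found: {data_dir}")
    profiles = {}
    for trait in TRAITS:
        p = data_dir / f"traits_{trait}.tsv"
        if not p.exists():
            raise FileNotFoundError(f"missing trait table: {p}")
        profiles[trait] = read_trait_table(p, trait)
    tree_path = data_dir / "tree.nwk"
    if not tree_path.exists():
        raise FileNotFoundError(f"missing tree file: {tree_path}")
    tree = Phylogeny.from_file(tree_path)
    clades = None
    if (data_dir / "clades.tsv").exists():
        clades = read_clades(data_dir / "clades.tsv")
    return profiles, tree, clades
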