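"""Landmark superimposition and the specimen-by-descriptor shape table.

Generalized Procrustes analysis (GPA) removes position, orientation and
(optionally) scale from 3D landmark configurations so that the residual
coordinates are pure shape.  Aligned configurations are flattened into a
:class:`ShapeTable` — the common currency of ordination, classification
and regression downstream — which equally accepts externally produced
deformation-descriptor vectors (e.g. diffeomorphic momenta), tagged by
provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkConfig",
    "ShapeTable",
    "gpa",
    "flatten",
    "species_means",
    "read_landmarks",
    "write_landmarks",
]

_LABEL_COLS = ["specimen", "species", "group"]


@dataclass
class LandmarkConfig:
    """One specimen's k x 3 landmark configuration (dimensionless after scaling)."""

    specimen: str
    coords: np.ndarray = field(repr=False)
    side: str | None = None  # "left" | "right" | None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be a (k, 3) array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates in specimen {self.specimen!r}")

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    def centroid_size(self) -> float:
        centered = self.coords - self.coords.mean(axis=0)
        return float(np.sqrt((centered**2).sum()))


class ShapeTable:
    """Specimens x descriptors with specimen / species / group labels.

    ``provenance`` records whether descriptor columns are flattened aligned
    landmarks (``"landmark"``) or externally computed deformation
    descriptors (``"deformation"``); back-projection to configurations is
    only meaningful for the former.
    """

    def __init__(self, df: pd.DataFrame, provenance: str = "deformation"):
        missing = [c for c in _LABEL_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"missing label columns: {missing}")
        if df[_LABEL_COLS].isna().any().any():
            raise ValueError("specimen/species/group labels must be complete")
        if provenance not in ("landmark", "deformation"):
            raise ValueError("provenance must be 'landmark' or 'deformation'")
        self.df = df.reset_index(drop=True)
        self.provenance = provenance

    # -- constructors --------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        X: np.ndarray,
        specimens,
        species,
        groups,
        provenance: str = "deformation",
        descriptor_names: list[str] | None = None,
    ) -> "ShapeTable":
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        for name, labels in (("specimens", specimens), ("species", species), ("groups", groups)):
            if len(labels) != n:
                raise ValueError(f"{name} has {len(labels)} labels for {n} rows")
        if descriptor_names is None:
            descriptor_names = [f"d{j}" for j in range(p)]
        df = pd.DataFrame(X, columns=descriptor_names)
        df.insert(0, "group", list(groups))
        df.insert(0, "species", list(species))
        df.insert(0, "specimen", list(specimens))
        return cls(df, provenance=provenance)

    @classmethod
    def read(cls, path, provenance: str = "deformation") -> "ShapeTable":
        return cls(pd.read_csv(path, sep="\t"), provenance=provenance)

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    # -- accessors ------------------------------------------------------

    @property
    def descriptor_names(self) -> list[str]:
        return [c for c in self.df.columns if c not in _LABEL_COLS]

    @property
    def X(self) -> np.ndarray:
        return self.df[self.descriptor_names].to_numpy(dtype=float)

    @property
    def specimens(self) -> pd.Series:
        return self.df["specimen"]

    @property
    def species(self) -> pd.Series:
        return self.df["species"]

    @property
    def groups(self) -> pd.Series:
        return self.df["group"]

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def p(self) -> int:
        return len(self.descriptor_names)

    def subset(self, mask) -> "ShapeTable":
        return ShapeTable(self.df.loc[mask].reset_index(drop=True), self.provenance)

    def require_min_group_size(self, k: int = 2) -> None:
        small = self.df.groupby("group").size()
        small = small[small < k]
        if len(small):
            raise ValueError(
                f"groups with fewer than {k} specimens: {sorted(small.index)}"
            )

    def __repr__(self) -> str:
        g = self.df["group"].nunique()
        return (
            f"ShapeTable(n={self.n}, p={self.p}, groups={g}, "
            f"provenance={self.provenance!r})"
        )


# ---------------------------------------------------------------------------
# Generalized Procrustes analysis
# ---------------------------------------------------------------------------


def _optimal_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Proper rotation R minimising ||A R - B||_F (Kabsch, det(R) = +1)."""
    U, _, Vt = np.linalg.svd(A.T @ B)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    return U @ D @ Vt


def _prepare(config: LandmarkConfig, allow_scaling: bool, mirror: bool) -> np.ndarray:
    coords = config.coords.copy()
    if mirror and config.side == "right":
        coords[:, 0] = -coords[:, 0]
    coords -= coords.mean(axis=0)
    size = np.sqrt((coords**2).sum())
    if size == 0:
        raise ValueError(
            f"degenerate configuration (coincident landmarks): {config.specimen!r}"
        )
    if allow_scaling:
        coords /= size
    return coords


def gpa(
    configs: list[LandmarkConfig],
    allow_scaling: bool = True,
    mirror: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[list[LandmarkConfig], LandmarkConfig]:
    """Generalized Procrustes superimposition.

    Each configuration is centred at the origin, scaled to unit centroid
    size when ``allow_scaling`` (the package's scale convention), mirrored
    across the x-axis when flagged right-sided and ``mirror`` is on, and
    rotated to the iteratively refined consensus.  Iteration stops when the
    consensus moves by less than ``tol`` (RMS) or after ``max_iter`` rounds.

    Returns the aligned configurations and the consensus (their
    coordinate-wise mean).
    """
    if len(configs) < 2:
        raise ValueError("GPA needs at least two configurations")
    ks = {c.k for c in configs}
    if len(ks) != 1:
        raise ValueError(f"landmark counts differ across configurations: {sorted(ks)}")

    shapes = [_prepare(c, allow_scaling, mirror) for c in configs]
    consensus = shapes[0].copy()
    for _ in range(max_iter):
        shapes = [s @ _optimal_rotation(s, consensus) for s in shapes]
        new_consensus = np.mean(shapes, axis=0)
        # keep the consensus on the same scale as the data
        if allow_scaling:
            size = np.sqrt((new_consensus**2).sum())
            if size > 0:
                new_consensus = new_consensus / size
        shift = np.sqrt(np.mean((new_consensus - consensus) ** 2))
        consensus = new_consensus
        if shift < tol:
            break
    # final pass so every shape is aligned to the converged consensus
    shapes = [s @ _optimal_rotation(s, consensus) for s in shapes]
    consensus = np.mean(shapes, axis=0)

    aligned = [
        LandmarkConfig(c.specimen, s, side=c.side) for c, s in zip(configs, shapes)
    ]
    return aligned, LandmarkConfig("consensus", consensus)


def procrustes_distance(a: LandmarkConfig, b: LandmarkConfig) -> float:
    """Root-mean-square deviation between two (already aligned) configurations."""
    return float(np.sqrt(np.mean((a.coords - b.coords) ** 2)))


def flatten(
    aligned: list[LandmarkConfig],
    species,
    groups,
) -> ShapeTable:
    """Row-bind aligned configurations into a ShapeTable (p = 3k).

    Row i is specimen i's landmarks concatenated as (x, y, z) per landmark.
    """
    n = len(aligned)
    if len(species) != n or len(groups) != n:
        raise ValueError(
            f"label count mismatch: {n} specimens, {len(species)} species, "
            f"{len(groups)} groups"
        )
    k = aligned[0].k
    X = np.stack([c.coords.reshape(-1) for c in aligned])
    names = [f"lm{i}_{ax}" for i in range(k) for ax in "xyz"]
    return ShapeTable.from_arrays(
        X,
        specimens=[c.specimen for c in aligned],
        species=list(species),
        groups=list(groups),
        provenance="landmark",
        descriptor_names=names,
    )


def species_means(table: ShapeTable) -> ShapeTable:
    """Collapse specimens to one arithmetic-mean row per species.

    Signal statistics and PGLS operate on one value per tree tip, so the
    per-specimen table is reduced to species means; the group label is
    inherited (species never straddle groups in this design).
    """
    rows = []
    for sp, sub in table.df.groupby("species", sort=True):
        groups = sub["group"].unique()
        if len(groups) != 1:
            raise ValueError(f"species {sp!r} spans multiple groups: {list(groups)}")
        mean = sub[table.descriptor_names].mean(axis=0)
        rows.append({"specimen": sp, "species": sp, "group": groups[0], **mean})
    return ShapeTable(pd.DataFrame(rows), provenance=table.provenance)


# ---------------------------------------------------------------------------
# Landmark file I/O: wide table, one row per specimen
# ---------------------------------------------------------------------------


def read_landmarks(path) -> list[LandmarkConfig]:
    """Read a delimited landmark table (specimen[, side], lm0_x, lm0_y, ...)."""
    df = pd.read_csv(path, sep="\t")
    if "specimen" not in df.columns:
        raise ValueError("landmark table must have a 'specimen' column")
    has_side = "side" in df.columns
    coord_cols = [c for c in df.columns if c not in ("specimen", "side")]
    if len(coord_cols) % 3:
        raise ValueError("coordinate columns are not a multiple of 3")
    configs = []
    for _, row in df.iterrows():
        coords = row[coord_cols].to_numpy(dtype=float).reshape(-1, 3)
        side = row["side"] if has_side and pd.notna(row["side"]) else None
        configs.append(LandmarkConfig(str(row["specimen"]), coords, side=side))
    return configs


def write_landmarks(configs: list[LandmarkConfig], path) -> None:
    k = configs[0].k
    cols = [f"lm{i}_{ax}" for i in range(k) for ax in "xyz"]
    rows = []
    for c in configs:
        rows.append(
            {"specimen": c.specimen, "side": c.side or "", **dict(zip(cols, c.coords.reshape(-1)))}
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
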