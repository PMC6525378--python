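"""Readers, writers and validators for landmark-based morphometric inputs.

Supported on-disk formats:

* landmark coordinates — plain whitespace matrix text (``n_points`` rows of
  three columns per specimen, specimens stacked) or a TPS dialect with
  ``LM3=`` blocks and ``ID=`` lines; output additionally as wide CSV
  (specimen x point_axis);
* slider definitions — whitespace/CSV triples (before, slide, after),
  1-based as in the usual landmark numbering, converted to 0-based on read;
* bilateral symmetry pairs — whitespace/CSV (left, right) index pairs;
* phylogeny — Newick or simple Nexus via dendropy, pruned to the study taxa;
* specimen metadata — CSV with columns ``species, clade, diet``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .phylo_stats import Phylogeny

FIXED = "fixed"
SEMILANDMARK = "semilandmark"

#: EltonTraits-style preferred-food categories recoded by mechanical
#: resistivity of the preferred food items.
DIET_RECODING = {
    "plant/seed": "MMR",
    "omnivore": "mixed",
    "fruit/nectar": "LMR",
}


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Landmark containers
# ---------------------------------------------------------------------------


@dataclass
class LandmarkSet:
    """Per-specimen 3D landmark configurations with point roles.

    ``coords`` has shape (n_specimens, n_points, 3).  ``point_roles`` tags
    each point as a fixed landmark or a sliding semilandmark;
    ``curve_membership`` assigns each semilandmark to a curve (−1 for fixed
    points).
    """

    specimen_ids: list[str]
    coords: np.ndarray
    point_roles: np.ndarray = field(default=None)  # type: ignore[assignment]
    curve_membership: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_specimens, n_points, 3)")
        if len(self.specimen_ids) != self.coords.shape[0]:
            raise ValueError("specimen_ids length does not match coords")
        if len(set(self.specimen_ids)) != len(self.specimen_ids):
            raise ValueError("specimen_ids must be unique")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        n_pts = self.coords.shape[1]
        if self.point_roles is None:
            self.point_roles = np.array([FIXED] * n_pts)
        self.point_roles = np.asarray(self.point_roles)
        if self.curve_membership is None:
            self.curve_membership = np.full(n_pts, -1, dtype=int)
        self.curve_membership = np.asarray(self.curve_membership, dtype=int)
        if len(self.point_roles) != n_pts or len(self.curve_membership) != n_pts:
            raise ValueError("per-point annotations do not match n_points")

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def n_points(self) -> int:
        return self.coords.shape[1]

    def flattened(self) -> np.ndarray:
        """(n_specimens, 3*n_points) row-per-specimen matrix (x,y,z per point)."""
        return self.coords.reshape(self.n_specimens, -1)


@dataclass
class SliderDefinition:
    """Neighbour triples (before, slide, after) for tangent-direction sliding."""

    triples: np.ndarray  # (m, 3) int, 0-based

    def __post_init__(self) -> None:
        self.triples = np.asarray(self.triples, dtype=int).reshape(-1, 3)

    def validate(self, landmarks: LandmarkSet) -> None:
        t = self.triples
        n = landmarks.n_points
        if t.size and (t.min() < 0 or t.max() >= n):
            raise ValueError(f"slider index out of range for {n} points")
        sliders = t[:, 1]
        if len(np.unique(sliders)) != len(sliders):
            raise ValueError("duplicate slider indices")
        if np.any(t[:, 1] == t[:, 0]) or np.any(t[:, 1] == t[:, 2]):
            raise ValueError("a slider cannot be its own neighbour")
        roles = landmarks.point_roles[sliders]
        bad = sliders[roles != SEMILANDMARK]
        if bad.size:
            raise ValueError(f"slider indices not tagged semilandmark: {bad.tolist()}")


@dataclass
class SymmetryMap:
    """Bilateral landmark pairing; every point is paired or on the midline."""

    pairs: np.ndarray  # (k, 2) int, 0-based
    midline: np.ndarray  # (m,) int

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.midline = np.asarray(self.midline, dtype=int).reshape(-1)

    def validate(self, n_points: int) -> None:
        seen = np.concatenate([self.pairs.ravel(), self.midline])
        if sorted(seen.tolist()) != list(range(n_points)):
            raise ValueError("pairs and midline must cover every point exactly once")


# ---------------------------------------------------------------------------
# Landmark I/O
# ---------------------------------------------------------------------------

_TPS_LM = re.compile(r"^LM3?\s*=\s*(\d+)", re.IGNORECASE)
_TPS_ID = re.compile(r"^ID\s*=\s*(.+)", re.IGNORECASE)


def _read_tps(lines: list[str]) -> tuple[list[str], list[np.ndarray]]:
    ids: list[str] = []
    blocks: list[np.ndarray] = []
    i = 0
    while i < len(lines):
        m = _TPS_LM.match(lines[i].strip())
        if not m:
            i += 1
            continue
        n = int(m.group(1))
        rows = []
        i += 1
        while len(rows) < n and i < len(lines):
            s = lines[i].strip()
            i += 1
            if not s or _TPS_ID.match(s) or _TPS_LM.match(s):
                raise ParseError(
                    f"specimen {len(blocks) + 1}: expected {n} coordinate rows, got {len(rows)}"
                )
            try:
                rows.append([float(v) for v in s.split()])
            except ValueError as e:
                raise ParseError(f"non-numeric token near line {i}: {s!r}") from e
        if len(rows) < n:
            raise ParseError(f"specimen {len(blocks) + 1}: truncated block ({len(rows)}/{n} rows)")
        spec_id = None
        while i < len(lines):
            s = lines[i].strip()
            mid = _TPS_ID.match(s)
            if mid:
                spec_id = mid.group(1).strip()
                i += 1
                break
            if _TPS_LM.match(s):
                break
            i += 1
        ids.append(spec_id if spec_id else f"specimen_{len(blocks) + 1}")
        blocks.append(np.asarray(rows, dtype=float))
    return ids, blocks


def read_landmarks(
    path: str | Path,
    n_fixed: int,
    n_semi: int,
    specimen_ids: list[str] | None = None,
    curve_membership: np.ndarray | None = None,
) -> LandmarkSet:
    """Read a landmark file (whitespace matrix or TPS dialect).

    The first ``n_fixed`` rows of each specimen block are fixed landmarks,
    the remaining ``n_semi`` are semilandmarks.  For the plain matrix
    format, specimen labels come from ``specimen_ids`` (or are generated).
    """
    path = Path(path)
    n_points = n_fixed + n_semi
    text = path.read_text()
    lines = text.splitlines()
    if any(_TPS_LM.match(ln.strip()) for ln in lines[:5]):
        ids, blocks = _read_tps(lines)
        if not blocks:
            raise ParseError("no specimens")
        for k, b in enumerate(blocks):
            if b.shape != (n_points, 3):
                raise ParseError(
                    f"specimen {k + 1} ({ids[k]}): expected {n_points}x3 block, got {b.shape}"
                )
        coords = np.stack(blocks)
        if specimen_ids is not None:
            ids = list(specimen_ids)
    else:
        rows = []
        for ln_no, s in enumerate(lines, 1):
            s = s.strip()
            if not s or s.startswith("#"):
                continue
            toks = s.replace(",", " ").split()
            try:
                rows.append([float(v) for v in toks])
            except ValueError as e:
                raise ParseError(f"non-numeric token at line {ln_no}: {s!r}") from e
        if not rows:
            raise ParseError("no specimens")
        arr = np.asarray(rows, dtype=float)
        if arr.shape[1] != 3:
            raise ParseError(f"expected 3 columns, got {arr.shape[1]}")
        if arr.shape[0] % n_points != 0:
            bad = arr.shape[0] // n_points + 1
            raise ParseError(
                f"specimen {bad}: file has {arr.shape[0]} rows, not a multiple of {n_points}"
            )
        coords = arr.reshape(-1, n_points, 3)
        ids = (
            list(specimen_ids)
            if specimen_ids is not None
            else [f"specimen_{k + 1}" for k in range(coords.shape[0])]
        )
    roles = np.array([FIXED] * n_fixed + [SEMILANDMARK] * n_semi)
    return LandmarkSet(ids, coords, roles, curve_membership)


def write_landmarks(landmarks: LandmarkSet, path: str | Path, fmt: str = "matrix") -> None:
    """Write landmarks as plain matrix text, TPS dialect, or wide CSV."""
    path = Path(path)
    if fmt == "matrix":
        with path.open("w") as fh:
            for spec in landmarks.coords:
                for p in spec:
                    fh.write(f"{float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n")
    elif fmt == "tps":
        with path.open("w") as fh:
            for sid, spec in zip(landmarks.specimen_ids, landmarks.coords):
                fh.write(f"LM3={landmarks.n_points}\n")
                for p in spec:
                    fh.write(f"{float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n")
                fh.write(f"ID={sid}\n")
    elif fmt == "csv":
        cols = [f"p{i + 1}_{ax}" for i in range(landmarks.n_points) for ax in "xyz"]
        pd.DataFrame(landmarks.flattened(), index=landmarks.specimen_ids, columns=cols).to_csv(
            path, index_label="specimen"
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _read_index_table(path: str | Path, n_cols: int) -> np.ndarray:
    rows = []
    for s in Path(path).read_text().splitlines():
        s = s.strip()
        if not s or s.startswith("#"):
            continue
        toks = s.replace(",", " ").split()
        if not all(re.fullmatch(r"-?\d+", t) for t in toks):
            continue  # header line
        if len(toks) != n_cols:
            raise ParseError(f"expected {n_cols} columns, got {len(toks)}: {s!r}")
        rows.append([int(t) for t in toks])
    return np.asarray(rows, dtype=int).reshape(-1, n_cols)


def read_sliders(path: str | Path, one_based: bool = True) -> SliderDefinition:
    t = _read_index_table(path, 3)
    return SliderDefinition(t - 1 if one_based else t)


def read_symmetry_pairs(path: str | Path, n_points: int, one_based: bool = True) -> SymmetryMap:
    p = _read_index_table(path, 2)
    if one_based:
        p = p - 1
    paired = set(p.ravel().tolist())
    midline = np.array([i for i in range(n_points) if i not in paired], dtype=int)
    sym = SymmetryMap(p, midline)
    sym.validate(n_points)
    return sym


# ---------------------------------------------------------------------------
# Semilandmark curve resampling
# ---------------------------------------------------------------------------


def resample_curve(points: np.ndarray, k: int) -> np.ndarray:
    """Resample an open 3D polyline to ``k`` points equally spaced in arc
    length, preserving both endpoints."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 input points")
    if k < 2:
        raise ValueError("k must be >= 2")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seg.sum()
    if total <= 0:
        raise ValueError("curve has zero length (duplicate consecutive points)")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, k)
    out = np.empty((k, pts.shape[1]))
    out[0] = pts[0]
    out[-1] = pts[-1]
    for i, t in enumerate(targets[1:-1], 1):
        j = int(np.searchsorted(cum, t, side="right") - 1)
        j = min(j, len(seg) - 1)
        frac = (t - cum[j]) / seg[j] if seg[j] > 0 else 0.0
        out[i] = pts[j] + frac * (pts[j + 1] - pts[j])
    return out


# ---------------------------------------------------------------------------
# Metadata and diet recoding
# ---------------------------------------------------------------------------


def recode_diet(elton_category: str) -> str:
    """Map a preferred-food category to its mechanical-resistivity class.

    plant/seed -> MMR (more mechanically resistant), omnivore -> mixed,
    fruit/nectar -> LMR (less mechanically resistant).
    """
    key = elton_category.strip().lower()
    if key not in DIET_RECODING:
        raise ValueError(
            f"unknown diet category {elton_category!r}; accepted: {sorted(DIET_RECODING)}"
        )
    return DIET_RECODING[key]


def normalize_name(name: str) -> str:
    return name.strip().lower().replace("_", " ")


def read_metadata(path: str | Path, recode: bool = False) -> pd.DataFrame:
    """Read specimen metadata CSV with columns species, clade, diet.

    With ``recode=True``, the diet column holds raw preferred-food
    categories and is recoded to MMR/mixed/LMR.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = {"species", "clade", "diet"} - set(df.columns)
    if missing:
        raise ParseError(f"metadata missing columns: {sorted(missing)}")
    if recode:
        df["diet"] = df["diet"].map(recode_diet)
    bad = set(df["diet"]) - {"MMR", "mixed", "LMR"}
    if bad:
        raise ParseError(f"unrecognised diet labels {sorted(bad)}; expected MMR/mixed/LMR")
    return df


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def read_tree(path: str | Path, tip_labels: list[str] | None = None) -> Phylogeny:
    """Read a Newick/Nexus tree and prune it to the study taxa.

    Tip matching is case-insensitive with underscores equivalent to spaces;
    requested tips absent from the tree are a hard error (silent dropping
    would corrupt the phylogenetic covariance matrix).
    """
    path = Path(path)
    text = path.read_text()
    schema = "nexus" if text.lstrip().lower().startswith("#nexus") else "newick"
    tree = dendropy.Tree.get(path=str(path), schema=schema)
    by_norm: dict[str, str] = {}
    for lf in tree.leaf_node_iter():
        by_norm[normalize_name(lf.taxon.label)] = lf.taxon.label
    if tip_labels is None:
        order = [lf.taxon.label for lf in tree.leaf_node_iter()]
        return Phylogeny(tree, order)
    missing = [t for t in tip_labels if normalize_name(t) not in by_norm]
    if missing:
        raise ValueError(f"tips missing from tree: {missing}")
    keep_native = [by_norm[normalize_name(t)] for t in tip_labels]
    tree.retain_taxa([tx for tx in tree.taxon_namespace if tx.label in set(keep_native)])
    for e in tree.preorder_edge_iter():
        if e.length is not None and e.length <= 0 and e.head_node.parent_node is not None:
            import logging

            logging.getLogger(__name__).warning(
                "branch of non-positive length %s retained", e.length
            )
    # relabel tips back to the caller's spelling so downstream joins are exact
    native_to_req = {by_norm[normalize_name(t)]: t for t in tip_labels}
    for lf in tree.leaf_node_iter():
        lf.taxon.label = native_to_req[lf.taxon.label]
    return Phylogeny(tree, list(tip_labels))
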