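"""Readers and writers for landmark data, trees, hypothesis ledgers and pairings.

Canonical interchange format for landmark coordinates is long-form CSV with
columns ``specimen,landmark,x,y,z``; TPS (3D, ``LM3=`` blocks) is supported
for interoperability.  Trees are Newick.  Hypothesis ledgers and symmetry
pairings are YAML.  Coordinates are treated as unitless; no unit metadata is
parsed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class LandmarkDataset:
    """A set of landmark configurations: S specimens x P landmarks x 3 coordinates.

    Landmark order is the single source of truth: every downstream matrix
    uses contiguous (landmark x 3) column blocks in this order.
    """

    specimen_labels: list[str]
    landmark_labels: list[str]
    coords: np.ndarray  # (S, P, 3)
    aligned: bool = False
    centroid_sizes: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be (S, P, 3), got {self.coords.shape}")
        s, p, _ = self.coords.shape
        if len(self.specimen_labels) != s:
            raise ValueError("specimen_labels length does not match coords")
        if len(self.landmark_labels) != p:
            raise ValueError("landmark_labels length does not match coords")
        if len(set(self.specimen_labels)) != s:
            raise ValueError("specimen labels must be unique")
        if len(set(self.landmark_labels)) != p:
            raise ValueError("landmark labels must be unique")
        if not np.all(np.isfinite(self.coords)):
            bad = [self.specimen_labels[i] for i in sorted(set(np.argwhere(~np.isfinite(self.coords))[:, 0]))]
            raise ValueError(f"non-finite coordinates for specimens: {bad}")
        if p < 4:
            raise ValueError(f"need at least 4 landmarks, got {p}")
        if self.aligned:
            cent = self.coords.mean(axis=1)
            if np.abs(cent).max() > 1e-8:
                raise ValueError("aligned dataset must have centroids at the origin")
            if self.centroid_sizes is None:
                raise ValueError("aligned dataset must record centroid sizes")
        if self.centroid_sizes is not None:
            self.centroid_sizes = np.asarray(self.centroid_sizes, dtype=float)
            if self.centroid_sizes.shape != (s,) or np.any(self.centroid_sizes <= 0):
                raise ValueError("centroid_sizes must be length-S positive reals")

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]

    def flat(self) -> np.ndarray:
        """Coordinates as an S x 3P matrix with landmark-contiguous column blocks."""
        s, p, _ = self.coords.shape
        return self.coords.reshape(s, 3 * p)

    def subset_specimens(self, labels: Sequence[str]) -> "LandmarkDataset":
        idx = [self.specimen_labels.index(l) for l in labels]
        cs = self.centroid_sizes[idx] if self.centroid_sizes is not None else None
        return LandmarkDataset(list(labels), list(self.landmark_labels), self.coords[idx], self.aligned, cs)


@dataclass
class SymmetryPairing:
    """Bilateral object-symmetry bookkeeping: left/right landmark pairs plus midline landmarks."""

    paired: list[tuple[str, str]]
    midline: list[str]

    def validate(self, landmark_labels: Sequence[str]) -> None:
        mentioned: list[str] = list(self.midline)
        for l, r in self.paired:
            mentioned.extend((l, r))
        labels = set(landmark_labels)
        counts = pd.Series(mentioned).value_counts()
        dups = counts[counts > 1].index.tolist()
        if dups:
            raise ValueError(f"landmarks appear more than once in pairing: {sorted(dups)}")
        extra = sorted(set(mentioned) - labels)
        if extra:
            raise ValueError(f"pairing mentions unknown landmarks: {extra}")
        missing = sorted(labels - set(mentioned))
        if missing:
            raise ValueError(f"landmarks not covered by pairing: {missing}")

    def swap_indices(self, landmark_labels: Sequence[str]) -> np.ndarray:
        """Permutation that exchanges each left landmark with its right partner."""
        self.validate(landmark_labels)
        pos = {lab: i for i, lab in enumerate(landmark_labels)}
        perm = np.arange(len(landmark_labels))
        for l, r in self.paired:
            perm[pos[l]], perm[pos[r]] = pos[r], pos[l]
        return perm


# ---------------------------------------------------------------------------
# landmark coordinate IO


def read_landmarks(path: str | Path, format: str = "csv_long") -> LandmarkDataset:
    """Read a landmark dataset from CSV (long) or TPS.

    The CSV dialect has one row per (specimen, landmark) with columns
    ``specimen,landmark,x,y,z``.  All specimens must share the same landmark
    set; ragged or duplicated entries are format errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv_long":
        return _read_csv_long(path)
    if format == "tps":
        return _read_tps(path)
    raise ValueError(f"unknown landmark format {format!r}")


def _read_csv_long(path: Path) -> LandmarkDataset:
    df = pd.read_csv(path, dtype={"specimen": str, "landmark": str},
                     float_precision="round_trip")
    required = {"specimen", "landmark", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    dup = df.duplicated(subset=["specimen", "landmark"])
    if dup.any():
        rows = df.loc[dup, ["specimen", "landmark"]].drop_duplicates()
        raise FormatError(f"{path}: duplicate (specimen, landmark) rows: {rows.values.tolist()}")

    specimens = list(dict.fromkeys(df["specimen"]))
    landmarks = list(dict.fromkeys(df["landmark"]))
    lm_set = set(landmarks)
    coords = np.full((len(specimens), len(landmarks), 3), np.nan)
    lm_pos = {l: j for j, l in enumerate(landmarks)}
    sp_pos = {s: i for i, s in enumerate(specimens)}
    for (sp, lm), row in df.set_index(["specimen", "landmark"]).iterrows():
        coords[sp_pos[sp], lm_pos[lm]] = (row["x"], row["y"], row["z"])
    for sp in specimens:
        present = set(df.loc[df["specimen"] == sp, "landmark"])
        missing = sorted(lm_set - present)
        if missing:
            raise FormatError(f"{path}: specimen {sp!r} is missing landmarks {missing}")
    return LandmarkDataset(specimens, landmarks, coords)


def _read_tps(path: Path) -> LandmarkDataset:
    specimens: list[str] = []
    blocks: list[np.ndarray] = []
    cur: list[list[float]] = []
    expected = None
    cur_id = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            up = line.upper()
            if up.startswith("LM3=") or up.startswith("LM="):
                if expected is not None:
                    raise FormatError(f"{path}: LM block before previous ID line")
                expected = int(line.split("=", 1)[1])
                cur = []
            elif up.startswith("ID="):
                cur_id = line.split("=", 1)[1]
                if expected is None:
                    raise FormatError(f"{path}: ID line without LM block")
                if len(cur) != expected:
                    raise FormatError(
                        f"{path}: specimen {cur_id!r} has {len(cur)} landmarks, expected {expected}"
                    )
                specimens.append(cur_id)
                blocks.append(np.array(cur))
                expected, cur, cur_id = None, [], None
            else:
                parts = line.split()
                if len(parts) != 3:
                    raise FormatError(f"{path}: bad coordinate line {line!r}")
                cur.append([float(v) for v in parts])
    if expected is not None:
        raise FormatError(f"{path}: trailing LM block without ID line")
    counts = {b.shape[0] for b in blocks}
    if len(counts) > 1:
        ragged = [s for s, b in zip(specimens, blocks) if b.shape[0] != blocks[0].shape[0]]
        raise FormatError(f"{path}: ragged landmark counts for specimens {ragged}")
    p = blocks[0].shape[0]
    labels = [f"LM{i + 1}" for i in range(p)]
    return LandmarkDataset(specimens, labels, np.stack(blocks))


def write_landmarks_csv(dataset: LandmarkDataset, path: str | Path) -> None:
    rows = []
    for i, sp in enumerate(dataset.specimen_labels):
        for j, lm in enumerate(dataset.landmark_labels):
            x, y, z = dataset.coords[i, j]
            rows.append((sp, lm, x, y, z))
    df = pd.DataFrame(rows, columns=["specimen", "landmark", "x", "y", "z"])
    # repr-precision floats so that read -> write -> read is the identity
    df.to_csv(path, index=False, float_format="%.17g")


def write_landmarks_tps(dataset: LandmarkDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, sp in enumerate(dataset.specimen_labels):
            fh.write(f"LM3={dataset.n_landmarks}\n")
            for j in range(dataset.n_landmarks):
                x, y, z = (float(v) for v in dataset.coords[i, j])
                fh.write(f"{x!r} {y!r} {z!r}\n")
            fh.write(f"ID={sp}\n")


# ---------------------------------------------------------------------------
# trees


def read_tree(path: str | Path):
    """Read a rooted Newick tree with branch lengths into a :class:`~morphomod.phylo.Phylogeny`."""
    from morphomod.phylo import Phylogeny

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return Phylogeny.from_newick(path.read_text())


# ---------------------------------------------------------------------------
# hypothesis ledger and pairing configs (YAML)


def read_hypothesis_ledger(path: str | Path, landmark_labels: Optional[Sequence[str]] = None):
    """Read a hypothesis ledger mapping hypothesis name -> module -> landmark labels.

    Each hypothesis entry is ``{category: str, modules: {module: [landmark, ...]}}``.
    Every partition must be a set partition of the landmark labels; violations
    name the offending hypothesis and landmarks.
    """
    from morphomod.hypotheses import ModulePartition

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: ledger must be a mapping of hypothesis names")
    partitions = []
    for name, entry in raw.items():
        category = entry.get("category", "development")
        modules = {str(m): [str(l) for l in lms] for m, lms in entry["modules"].items()}
        part = ModulePartition(name=str(name), category=category, modules=modules)
        if landmark_labels is not None:
            part.validate(landmark_labels)
        partitions.append(part)
    return partitions


def write_hypothesis_ledger(partitions, path: str | Path) -> None:
    out = {
        p.name: {"category": p.category, "modules": {m: list(lms) for m, lms in p.modules.items()}}
        for p in partitions
    }
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False))


def read_symmetry_pairing(path: str | Path) -> SymmetryPairing:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text())
    paired = [(str(a), str(b)) for a, b in raw.get("paired", [])]
    midline = [str(m) for m in raw.get("midline", [])]
    return SymmetryPairing(paired=paired, midline=midline)


def write_symmetry_pairing(pairing: SymmetryPairing, path: str | Path) -> None:
    out = {"paired": [list(p) for p in pairing.paired], "midline": list(pairing.midline)}
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False))
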