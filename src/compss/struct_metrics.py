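"""Structure-derived metrics.

Solvent-accessible surface area (SASA) is computed with the Shrake-Rupley
rolling-probe algorithm: each atom's van der Waals sphere is expanded by the
probe radius (1.4 A, a water molecule) and covered with a quasi-uniform
Fibonacci point lattice; a point is accessible when it lies outside every
neighboring atom's expanded sphere, and the atom's area is the accessible
fraction of its expanded-sphere area.  Polar SASA restricts to N/O/S atoms,
apolar to the rest (carbon, mostly); percent polar = 100 x polar / total.

Mean per-residue confidence averages the per-residue values parsed from the
B-factor column (pLDDT for predicted structures).  Inverse-folding and
energy-function scorers are adapters: anything that maps (structure,
sequence) to a mean per-residue log-likelihood plugs in, with results cached
per (structure, sequence) pair.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .io import StructureModel

#: Heavy-atom van der Waals radii in Angstrom (Bondi 1964 set).
BONDI_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "H": 1.20, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "SE": 1.90, "ZN": 1.39, "CU": 1.40, "FE": 1.40, "MN": 1.40, "MG": 1.73,
}

#: Elements classified as polar for the SASA decomposition.
POLAR_ELEMENTS = frozenset({"N", "O", "S"})


@dataclass(frozen=True)
class RadiiSet:
    radii: dict = field(default_factory=lambda: dict(BONDI_RADII))
    probe: float = 1.4
    n_points: int = 960
    on_unknown_element: str = "error"  # or "skip"

    def radius(self, element: str) -> float | None:
        r = self.radii.get(element.upper())
        if r is None:
            if self.on_unknown_element == "skip":
                return None
            raise ValueError(f"unknown element {element!r}")
        return r


@dataclass(frozen=True)
class SasaResult:
    total: float
    polar: float
    apolar: float
    per_atom: tuple[float, ...]

    @property
    def percent_polar(self) -> float:
        return 100.0 * self.polar / self.total if self.total > 0 else 0.0


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the sphere (golden-spiral lattice)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley(structure: StructureModel,
                  radii_set: RadiiSet | None = None) -> SasaResult:
    """Per-atom solvent-accessible surface area with polar/apolar split.

    Atoms whose element is missing from the radii set either raise or are
    skipped (area 0, excluded as occluders), per ``on_unknown_element``.
    """
    radii_set = radii_set or RadiiSet()
    coords, radii, polar_mask, kept_index = [], [], [], []
    seen: set[tuple[float, float, float, float]] = set()
    for idx, atom in enumerate(structure.atoms):
        r = radii_set.radius(atom.element)
        if r is None:
            continue
        # exactly coincident atoms of equal radius contribute one surface
        key = (round(atom.x, 6), round(atom.y, 6), round(atom.z, 6), r)
        if key in seen:
            continue
        seen.add(key)
        coords.append([atom.x, atom.y, atom.z])
        radii.append(r + radii_set.probe)
        polar_mask.append(atom.element.upper() in POLAR_ELEMENTS)
        kept_index.append(idx)
    if not coords:
        raise ValueError("structure has no atoms with known elements")
    xyz = np.asarray(coords)
    rad = np.asarray(radii)
    sphere = _fibonacci_sphere(radii_set.n_points)

    per_atom = np.zeros(len(structure.atoms))
    # pairwise distances once; neighbor lists per atom
    d2 = ((xyz[:, None, :] - xyz[None, :, :]) ** 2).sum(-1)
    for i in range(len(xyz)):
        pts = xyz[i] + rad[i] * sphere
        reach2 = (rad[i] + rad) ** 2
        occluders = np.where((d2[i] < reach2) & (np.arange(len(xyz)) != i))[0]
        if occluders.size:
            diff = pts[:, None, :] - xyz[occluders][None, :, :]
            buried = (np.einsum("ijk,ijk->ij", diff, diff)
                      < rad[occluders] ** 2).any(axis=1)
            accessible = int((~buried).sum())
        else:
            accessible = radii_set.n_points
        area = 4.0 * np.pi * rad[i] ** 2 * accessible / radii_set.n_points
        per_atom[kept_index[i]] = area

    polar = float(sum(per_atom[kept_index[i]] for i in range(len(xyz)) if polar_mask[i]))
    total = float(per_atom.sum())
    return SasaResult(total=total, polar=polar, apolar=total - polar,
                      per_atom=tuple(per_atom))


def mean_confidence(structure: StructureModel, policy: str = "mean") -> float:
    """Unweighted mean of per-residue confidences (pLDDT for predictions)."""
    conf = structure.residue_confidence(policy)
    if not conf:
        raise ValueError("structure has no residues")
    if all(c == 0.0 for c in conf):
        raise ValueError("B-factor column is empty; confidence unavailable")
    return float(np.mean(conf))


def _structure_hash(structure: StructureModel) -> str:
    h = hashlib.sha256()
    for a in structure.atoms:
        h.update(f"{a.chain}|{a.res_seq}|{a.atom_name}|"
                 f"{a.x:.3f}|{a.y:.3f}|{a.z:.3f}".encode())
    return h.hexdigest()


class InverseFoldingScorer:
    """Adapter wrapper for structure-conditioned sequence scorers.

    ``adapter(structure, sequence)`` must return the mean per-residue
    log-likelihood of the sequence given the backbone.  Results are cached
    on (structure hash, sequence hash) so repeat queries never re-invoke the
    adapter.
    """

    def __init__(self, adapter: Callable[[StructureModel, str], float]) -> None:
        self.adapter = adapter
        self._cache: dict[tuple[str, str], float] = {}
        self.n_calls = 0

    def score(self, structure: StructureModel, sequence: str) -> float:
        if len(sequence) != len(structure):
            raise ValueError(
                f"sequence length {len(sequence)} != structure residue count "
                f"{len(structure)}")
        key = (_structure_hash(structure),
               hashlib.sha256(sequence.encode()).hexdigest())
        if key not in self._cache:
            self.n_calls += 1
            self._cache[key] = float(self.adapter(structure, sequence))
        return self._cache[key]


def inverse_folding_score(adapter, structure: StructureModel, sequence: str) -> float:
    """One-shot convenience over :class:`InverseFoldingScorer`."""
    if isinstance(adapter, InverseFoldingScorer):
        return adapter.score(structure, sequence)
    return InverseFoldingScorer(adapter).score(structure, sequence)


def parse_rosetta_scorefile(path) -> "pd.DataFrame":
    """Parse a Rosetta ``score.sc`` whitespace table into a DataFrame."""
    import pandas as pd
    rows, columns = [], None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("SCORE:"):
                continue
            parts = line.split()[1:]
            if columns is None:
                columns = parts
            else:
                rows.append(parts)
    if columns is None:
        raise ValueError(f"no SCORE: lines in {path}")
    df = pd.DataFrame(rows, columns=columns)
    for c in df.columns:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError):
            pass
    return df
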