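"""CA-trace structures, rigid superposition, GDT_TS and pLDDT evaluation.

GDT_TS (Global Distance Test, Total Score) is the mean over distance
cutoffs {1, 2, 4, 8} angstrom of the largest fraction of CA atoms that can
be brought within the cutoff of the reference by some rigid superposition,
times 100. The exact maximization is combinatorial; like the assessors'
scorers we use a deterministic seeded local search: superpose on a seed
subset, collect all residues within the cutoff, re-superpose on those, and
iterate to a fixed point; seeds are every contiguous window of length
3/5/7 along the shared residues plus the full common set, and the best
fraction over all seeds is reported. The search is exact for identical or
rigidly transformed structures and reproducible everywhere.

Predicted models store their per-residue confidence (pLDDT, 0-100) in the
PDB B-factor column; ``parse_ca`` reads it when asked.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import gemmi
import numpy as np

GDT_CUTOFFS = (1.0, 2.0, 4.0, 8.0)
CATEGORIES = ("FM", "FM/TBM", "TBM-hard", "TBM-easy")


@dataclass(frozen=True)
class StructureModel:
    """Ordered CA trace: residue numbers, coordinates (angstrom), optional pLDDT."""

    residue_numbers: np.ndarray  # (n,) int, strictly increasing
    coords: np.ndarray  # (n, 3) float
    plddt: np.ndarray | None = None  # (n,) float in [0, 100]

    def __post_init__(self):
        rn = np.asarray(self.residue_numbers, dtype=int)
        xyz = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "residue_numbers", rn)
        object.__setattr__(self, "coords", xyz)
        if self.plddt is not None:
            object.__setattr__(self, "plddt", np.asarray(self.plddt, dtype=float))
        if xyz.shape != (len(rn), 3):
            raise ValueError("coords must be (n, 3) matching residue_numbers")
        if len(rn) > 1 and not np.all(np.diff(rn) > 0):
            raise ValueError("residue numbers must be strictly increasing")
        if not np.all(np.isfinite(xyz)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.residue_numbers)

    def crop(self, residue_numbers: Sequence[int]) -> "StructureModel":
        """Subset to the given residue numbers (those present)."""
        wanted = set(int(r) for r in residue_numbers)
        mask = np.array([int(r) in wanted for r in self.residue_numbers])
        return StructureModel(
            residue_numbers=self.residue_numbers[mask],
            coords=self.coords[mask],
            plddt=None if self.plddt is None else self.plddt[mask],
        )


@dataclass(frozen=True)
class DomainDefinition:
    """A CASP evaluation unit: residue ranges of one domain plus its category."""

    target_id: str
    domain_id: str
    ranges: tuple[tuple[int, int], ...]  # inclusive 1-based intervals, sorted
    category: str = "FM"

    def __post_init__(self):
        rs = tuple((int(a), int(b)) for a, b in self.ranges)
        object.__setattr__(self, "ranges", rs)
        if any(a > b for a, b in rs):
            raise ValueError("interval start must not exceed end")
        for (a1, b1), (a2, b2) in zip(rs, rs[1:]):
            if a2 <= b1:
                raise ValueError("intervals must be sorted and non-overlapping")
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}")

    @property
    def residue_numbers(self) -> list[int]:
        out: list[int] = []
        for a, b in self.ranges:
            out.extend(range(a, b + 1))
        return out

    @classmethod
    def from_spec(cls, target_id: str, domain_id: str, ranges: str, category: str = "FM"):
        """Parse a range string like ``"10-120,140-160"``."""
        parsed = []
        for part in ranges.split(","):
            a, _, b = part.strip().partition("-")
            parsed.append((int(a), int(b or a)))
        return cls(target_id, domain_id, tuple(parsed), category)


@dataclass(frozen=True)
class Superposition:
    """Proper rigid transform x -> rotation @ x + translation, with its RMSD."""

    rotation: np.ndarray  # (3, 3), det +1
    translation: np.ndarray  # (3,)
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def parse_ca(pdb_text: str, predicted: bool = False) -> StructureModel:
    """Extract the CA trace from PDB-format text.

    One entry per residue carrying a CA atom; for altLoc variants the first
    occurrence wins. With ``predicted=True`` the B-factor column is read as
    per-residue pLDDT. Raises ``ValueError`` if no CA atoms are found or a
    residue number appears twice after altLoc resolution.
    """
    structure = gemmi.read_pdb_string(pdb_text)
    nums: list[int] = []
    xyz: list[tuple[float, float, float]] = []
    bfac: list[float] = []
    seen: set[int] = set()
    for model in structure:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    if atom.name != "CA" or atom.element.name == "Ca":
                        continue
                    num = residue.seqid.num
                    if num in seen:
                        raise ValueError(f"duplicate CA for residue {num}")
                    seen.add(num)
                    nums.append(num)
                    xyz.append((atom.pos.x, atom.pos.y, atom.pos.z))
                    bfac.append(atom.b_iso)
                    break  # first altLoc wins
        break  # first model only
    if not nums:
        raise ValueError("no CA atoms found")
    order = np.argsort(nums)
    return StructureModel(
        residue_numbers=np.array(nums)[order],
        coords=np.array(xyz)[order],
        plddt=np.array(bfac)[order] if predicted else None,
    )


def read_ca(path: str, predicted: bool = False) -> StructureModel:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_ca(fh.read(), predicted=predicted)


def write_ca(model: StructureModel, chain_id: str = "A") -> str:
    """Serialize a CA trace as PDB ATOM records (pLDDT in the B-factor column)."""
    lines = []
    for i, (num, (x, y, z)) in enumerate(zip(model.residue_numbers, model.coords), 1):
        b = 0.0 if model.plddt is None else float(model.plddt[i - 1])
        lines.append(
            f"ATOM  {i:5d}  CA  ALA {chain_id}{num:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b:6.2f}           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def kabsch(P: np.ndarray, Q: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of point set P onto Q.

    Returns the proper rotation (det +1; reflections excluded) and
    translation minimizing the RMSD of the transformed P to Q, by SVD of
    the covariance matrix. Requires at least 3 point pairs.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"point sets differ in shape: {P.shape} vs {Q.shape}")
    if P.shape[0] < 3:
        raise ValueError("superposition requires at least 3 points")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff**2).sum() / len(P)))
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


def _common(model: StructureModel, ref: StructureModel):
    common, im, ir = np.intersect1d(
        model.residue_numbers, ref.residue_numbers, return_indices=True
    )
    return common, model.coords[im], ref.coords[ir]


def gdt_fraction(model: StructureModel, ref: StructureModel, cutoff: float) -> float:
    """Largest found fraction of shared residues superposable within ``cutoff``.

    Seeded iterative search as described in the module docstring. Both
    structures must share at least 3 residue numbers; correspondence is by
    residue number (models are assumed renumbered to the reference).
    """
    common, P, Q = _common(model, ref)
    n = len(common)
    if n < 3:
        raise ValueError(f"only {n} common residues; need >= 3")

    seeds: list[np.ndarray] = [np.arange(n)]
    for w in (3, 5, 7):
        for start in range(0, n - w + 1):
            seeds.append(np.arange(start, start + w))

    best = 0.0
    visited: set[frozenset] = set()
    for seed in seeds:
        subset = seed
        for _ in range(10):
            key = frozenset(subset.tolist())
            if key in visited:
                break
            visited.add(key)
            sup = kabsch(P[subset], Q[subset])
            dist = np.linalg.norm(sup.apply(P) - Q, axis=1)
            new = np.flatnonzero(dist <= cutoff)
            if len(new) > 0:
                best = max(best, len(new) / n)
            if len(new) < 3 or np.array_equal(new, subset):
                break
            subset = new
    return best


def gdt_ts(
    model: StructureModel, ref: StructureModel, domain: DomainDefinition | None = None
) -> float:
    """GDT_TS in [0, 100]: 100 x mean gdt_fraction at 1/2/4/8 angstrom.

    With a domain definition, both structures are first cropped to the
    domain's residue ranges; at least 3 domain residues must be shared.
    """
    if domain is not None:
        nums = domain.residue_numbers
        model = model.crop(nums)
        ref = ref.crop(nums)
    return 100.0 * float(np.mean([gdt_fraction(model, ref, c) for c in GDT_CUTOFFS]))


def mean_plddt(model: StructureModel, domain: DomainDefinition | None = None) -> float:
    """Unweighted mean pLDDT over the domain's residues (or all residues)."""
    m = model if domain is None else model.crop(domain.residue_numbers)
    if m.plddt is None or len(m) == 0:
        raise ValueError("model carries no pLDDT for the requested residues")
    return float(np.mean(m.plddt))
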