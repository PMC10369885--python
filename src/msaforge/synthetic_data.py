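"""Synthetic inputs: homolog MSAs, CA decoy structures, server score tables.

Real inputs to this analysis are homology-search MSAs, predicted models
and CASP server score tables. This module generates stand-ins with
controlled properties so every stage runs without downloads:

* homolog sets with a chosen query-identity distribution — broad
  ``uniform(0.05, 1)`` pools emulate general-purpose sequence databases,
  while distributions truncated at 0.5 emulate petabase-scale read-mining
  hits, whose search tool cannot detect homologs below ~50% identity;
* decoy CA traces whose agreement with a reference (and hence GDT_TS)
  is controllable, with pLDDT written as a declared decreasing function
  of the per-residue deviation after superposition;
* Gaussian server GDT_TS fields for Z-score ranking.

All randomness flows through one ``numpy`` generator per call, seeded
explicitly, so every fixture is bitwise reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .msa_io import AlignedSequence, Msa
from .struct_eval import StructureModel, kabsch

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class HomologSimParams:
    """Controls for one simulated homolog pool.

    ``identity_dist`` is a named family with parameters:
    ``("point", t)``, ``("uniform", lo, hi)`` or
    ``("truncnorm", mean, sd, lo, hi)``; support must lie in [0, 1].
    ``indel_rate`` is the per-site probability of a deletion (a ``-`` in a
    match column) and, independently, of an insertion after the column.

    With ``n_founders`` set, homologs are not independent: that many
    founder lineages are drawn from ``identity_dist`` and each member is a
    near-copy of one founder (diverged at rate ``1 - within_id``). This
    emulates the redundancy of real homolog pools — databases hold many
    close relatives of few distinct lineages — so that a pool's diversity
    is limited by its lineage count, not its sequence count, and merging a
    pool that contributes *new* lineages raises N_eff the way adding new
    environmental clades does. ``n_founders=None`` gives the independent
    (star-tree) model.
    """

    n: int
    identity_dist: tuple = ("uniform", 0.05, 1.0)
    indel_rate: float = 0.0
    seed: int = 0
    n_founders: int | None = None
    within_id: float = 0.95

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.n_founders is not None and self.n_founders < 1:
            raise ValueError("n_founders must be >= 1 when set")
        if not 0.0 <= self.within_id <= 1.0:
            raise ValueError("within_id must lie in [0, 1]")
        if not 0.0 <= self.indel_rate <= 0.2:
            raise ValueError("indel_rate must lie in [0, 0.2]")
        fam = self.identity_dist[0]
        if fam not in ("point", "uniform", "truncnorm"):
            raise ValueError(f"unknown identity distribution family {fam!r}")
        lo, hi = self.support()
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("identity distribution support must lie within [0, 1]")

    def support(self) -> tuple[float, float]:
        fam, *p = self.identity_dist
        if fam == "point":
            return p[0], p[0]
        if fam == "uniform":
            return p[0], p[1]
        return p[2], p[3]

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        fam, *p = self.identity_dist
        if fam == "point":
            return np.full(size, float(p[0]))
        if fam == "uniform":
            return rng.uniform(p[0], p[1], size)
        mean, sd, lo, hi = p
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


@dataclass(frozen=True)
class DecoySpec:
    """Controls for one decoy structure.

    ``rigid``: random proper rotation + translation (a perfect model in a
    moved frame). ``noise``: i.i.d. Gaussian displacement of ``sigma``
    angstrom per coordinate. ``split_displace``: the first
    ``ceil(displace_fraction * L)`` residues kept exact, the rest moved
    ``displace_distance`` angstrom along a random direction and scrambled
    with 5 angstrom noise — yielding a GDT_TS close to 100 x fraction.
    """

    mode: str = "noise"
    sigma: float = 1.0
    displace_fraction: float = 0.5
    displace_distance: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("rigid", "noise", "split_displace"):
            raise ValueError(f"unknown decoy mode {self.mode!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0.0 <= self.displace_fraction <= 1.0:
            raise ValueError("displace_fraction must lie in [0, 1]")


def make_query(length: int, seed: int) -> str:
    """Uniform-random amino-acid sequence of the given length (>= 10)."""
    if length < 10:
        raise ValueError("query length must be >= 10")
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(_AA), size=length))


def simulate_homolog_msa(
    query: str, params: HomologSimParams
) -> tuple[Msa, list[float]]:
    """Simulate a query-anchored homolog MSA with known true identities.

    Each homolog draws a target identity t from ``identity_dist``, then
    substitutes every site independently with probability 1 - t to one of
    the 19 other residues; deletions replace match columns with ``-`` and
    insertions add lowercase residues after columns, each at
    ``indel_rate``. The generative alignment is emitted directly as A3M —
    no aligner is involved — and the sampled t values are returned.

    In clustered mode (``n_founders`` set) each member descends from a
    founder lineage and the returned t is its founder's identity.
    """
    rng = np.random.default_rng(params.seed)
    L = len(query)
    members: list[AlignedSequence] = [AlignedSequence("query", query)]
    qarr = np.frombuffer(query.encode(), dtype=np.uint8)
    aa = np.frombuffer(_AA.encode(), dtype=np.uint8)

    def mutate(base: np.ndarray, rate: float) -> np.ndarray:
        seq = base.copy()
        for j in np.flatnonzero(rng.random(L) < rate):
            choices = aa[aa != seq[j]]
            seq[j] = rng.choice(choices)
        return seq

    if params.n_founders is None:
        ts = params.sample(rng, params.n)
        bases = [mutate(qarr, 1.0 - t) for t in ts]
    else:
        founder_ts = params.sample(rng, params.n_founders)
        founders = [mutate(qarr, 1.0 - t) for t in founder_ts]
        picks = rng.integers(params.n_founders, size=params.n)
        ts = founder_ts[picks]
        bases = [mutate(founders[k], 1.0 - params.within_id) for k in picks]

    for i, seq in enumerate(bases):
        chars = [chr(c) for c in seq]
        if params.indel_rate > 0:
            dele = rng.random(L) < params.indel_rate
            ins = rng.random(L) < params.indel_rate
            out = []
            for j in range(L):
                out.append("-" if dele[j] else chars[j])
                if ins[j]:
                    out.append(str(rng.choice(list(_AA))).lower())
            chars = out
        members.append(AlignedSequence(f"hom{i:05d}", "".join(chars)))
    msa = Msa(query_id="query", members=tuple(members), L=L)
    msa.validate()
    return msa, [float(t) for t in ts]


def make_structure(length: int, seed: int) -> StructureModel:
    """Self-avoiding random CA trace, numbered 1..length.

    Consecutive CA-CA distances are 3.8 +- 0.1 angstrom; all
    non-consecutive pairs are at least 3.0 angstrom apart. Built as a
    persistent random walk with rejection of clashing steps.
    """
    if length < 10:
        raise ValueError("structure length must be >= 10")
    rng = np.random.default_rng(seed)

    def unit(v: np.ndarray) -> np.ndarray:
        return v / np.linalg.norm(v)

    while True:  # restart on the (rare) dead end
        pos = [np.zeros(3)]
        direction = unit(rng.standard_normal(3))
        ok = True
        for _ in range(length - 1):
            placed = False
            for _attempt in range(200):
                step = 3.8 + rng.uniform(-0.1, 0.1)
                cand_dir = unit(direction + 0.6 * rng.standard_normal(3))
                cand = pos[-1] + step * cand_dir
                if len(pos) >= 2:
                    d = np.linalg.norm(np.asarray(pos[:-1]) - cand, axis=1)
                    if d.min() < 3.0:
                        continue
                pos.append(cand)
                direction = cand_dir
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            break
    return StructureModel(
        residue_numbers=np.arange(1, length + 1), coords=np.asarray(pos)
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    # QR of a Gaussian matrix gives a Haar-random orthogonal matrix;
    # fix signs and determinant to get a proper rotation.
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def make_decoy(ref: StructureModel, spec: DecoySpec) -> StructureModel:
    """Perturb a reference CA trace into a decoy with assigned pLDDT.

    pLDDT is 100 * exp(-deviation / 4), clipped to [0, 100], where the
    deviation is the per-residue CA distance to the reference after
    optimal superposition of the decoy — so a rigidly moved but otherwise
    perfect decoy scores 100 everywhere, and accuracy and confidence agree
    by construction (disagreement cases are built by overriding pLDDT).
    """
    rng = np.random.default_rng(spec.seed)
    X = ref.coords.copy()
    n = len(ref)
    if spec.mode == "rigid":
        R = _random_rotation(rng)
        t = rng.uniform(-20.0, 20.0, 3)
        X = X @ R.T + t
    elif spec.mode == "noise":
        X = X + rng.normal(0.0, spec.sigma, size=X.shape)
    else:  # split_displace
        n_keep = math.ceil(spec.displace_fraction * n)
        shift = spec.displace_distance * unit_vector(rng)
        X[n_keep:] = X[n_keep:] + shift + rng.normal(0.0, 5.0, size=X[n_keep:].shape)
    sup = kabsch(X, ref.coords)
    deviation = np.linalg.norm(sup.apply(X) - ref.coords, axis=1)
    plddt = np.clip(100.0 * np.exp(-deviation / 4.0), 0.0, 100.0)
    return StructureModel(
        residue_numbers=ref.residue_numbers.copy(), coords=X, plddt=plddt
    )


def unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def make_server_scores(
    n_domains: int, n_servers: int, mean: float, sd: float, seed: int,
    domain_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Gaussian server GDT_TS fields, clipped to [0, 100].

    Returns a domain x server DataFrame; requires at least 2 servers.
    """
    if n_servers < 2:
        raise ValueError("need at least 2 servers")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    scores = np.clip(rng.normal(mean, sd, size=(n_domains, n_servers)), 0.0, 100.0)
    if domain_ids is None:
        domain_ids = [f"D{i + 1:03d}" for i in range(n_domains)]
    return pd.DataFrame(
        scores,
        index=domain_ids,
        columns=[f"server{j + 1:02d}" for j in range(n_servers)],
    )
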