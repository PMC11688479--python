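"""Seeded synthetic-data generators for every pipeline stage.

Each generator emulates the statistical structure its consumer assumes and
returns the planted ground truth alongside the data, enabling closed-loop
recovery tests without any download:

* compound libraries with k distinct chemotype families (template +
  substituent enumeration, so validity and the Tanimoto contrast between
  families are guaranteed by construction);
* activity sets whose label is the presence of a planted substructure,
  optionally corrupted by i.i.d. label noise;
* PPI graphs: Erdős–Rényi background plus one planted clique;
* gene universes with one term whose overlap with the query is exact;
* trajectories with per-block fluctuation amplitudes, an optional hinge
  mode giving inter-block motion correlation, and optional global
  rigid-motion contamination to exercise alignment.

One global seed fans out to per-stage child seeds by fixed offsets, so a
stage's output is reproducible even when other stages' parameters change.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .activity_ml import ActivityDataset
from .chemlib import CompoundRecord, CompoundSet, canonical_smiles
from .enrich import AnnotationCollection
from .fingerprints import CLUSTERING_MORGAN, compute_fingerprint, tanimoto
from .targetnet import GeneSet
from .trajstats import Trajectory

# Fixed per-stage seed offsets (stage-level reproducibility).
_STAGE_OFFSET = {
    "library": 101,
    "activity": 202,
    "ppi": 303,
    "genesets": 404,
    "trajectory": 505,
}


def child_seed(seed: int, stage: str) -> int:
    return (int(seed) * 1000 + _STAGE_OFFSET[stage]) % (2**31 - 1)


# ------------------------------------------------------------ compound library

# Three chemotype families mirroring a typical herbal library: a
# steroid/triterpene family, a flavonoid family, and an aporphine-like
# alkaloid family.  Substituent slots are filled from small vocabularies
# chosen so every substitution yields a valid SMILES.
_FLAVONOID_TEMPLATE = "{a}c1ccc(-c2oc3cc({b})cc(O)c3c(=O)c2{c})cc1"
_FLAVONOID_VOCAB = {
    "a": ["O", "CO", "C", "N", "F", "Cl", "OCCO"],
    "b": ["O", "OC", "C", "N", "F"],
    "c": ["O", "OC", "C"],
}
_ALKALOID_TEMPLATE = "CN1CCc2cc({a})c({b})cc2C1Cc1ccc({c})cc1"
_ALKALOID_VOCAB = {
    "a": ["O", "OC", "OCC", "C"],
    "b": ["O", "OC", "C", "F"],
    "c": ["O", "OC", "C", "N", "F"],
}
_STEROID_TEMPLATE = "{a}C(CCC(C)C1CCC2C1(CCC1C2CC=C2CC({b})CCC12C)C)C(C){c}"
_STEROID_VOCAB = {
    "a": ["C", "CC", "CCC", "C(C)C"],
    "b": ["O", "OC", "OCC"],
    "c": ["C", "CC", "O"],
}

FAMILY_TEMPLATES: dict[str, tuple[str, dict[str, list[str]]]] = {
    "flavonoid": (_FLAVONOID_TEMPLATE, _FLAVONOID_VOCAB),
    "alkaloid": (_ALKALOID_TEMPLATE, _ALKALOID_VOCAB),
    "steroid": (_STEROID_TEMPLATE, _STEROID_VOCAB),
}


def _family_variants(template: str, vocab: dict[str, list[str]]) -> list[str]:
    """Every valid canonical SMILES the template can produce, deduplicated."""
    keys = sorted(vocab)
    out: list[str] = []
    seen: set[str] = set()
    for combo in itertools.product(*(vocab[k] for k in keys)):
        smiles = template.format(**dict(zip(keys, combo)))
        canon = canonical_smiles(smiles)
        if canon is not None and canon not in seen:
            seen.add(canon)
            out.append(canon)
    return out


@dataclass(frozen=True)
class CompoundLibrary:
    compounds: CompoundSet
    family_labels: dict[str, str]  # compound id -> family name
    tanimoto_margin: float  # within-family mean minus between-family mean


def _library_margin(
    compounds: CompoundSet, labels: dict[str, str]
) -> float:
    fps = {
        r.id: compute_fingerprint(r, "morgan", CLUSTERING_MORGAN) for r in compounds
    }
    within, between = [], []
    recs = list(compounds)
    for i, a in enumerate(recs):
        for b in recs[i + 1 :]:
            sim = tanimoto(fps[a.id], fps[b.id])
            (within if labels[a.id] == labels[b.id] else between).append(sim)
    if not within or not between:
        return float("inf")
    return float(np.mean(within) - np.mean(between))


def gen_compound_library(
    seed: int,
    n_families: int = 3,
    family_size: int = 6,
    margin: float = 0.2,
    max_retries: int = 20,
) -> CompoundLibrary:
    """Generate a compound library with planted chemotype families.

    Members of each family are sampled (without replacement) from that
    family's template-variant pool; the draw is retried (bounded) until
    the within-family mean Tanimoto exceeds the between-family mean by at
    least ``margin``.  OB/DL descriptors are drawn inside the admission
    region so the library passes the ADME filter unchanged.
    """
    if n_families < 1 or n_families > len(FAMILY_TEMPLATES):
        raise ValueError(f"n_families must be in 1..{len(FAMILY_TEMPLATES)}")
    rng = np.random.default_rng(child_seed(seed, "library"))
    family_names = list(FAMILY_TEMPLATES)[:n_families]
    pools = {
        name: _family_variants(*FAMILY_TEMPLATES[name]) for name in family_names
    }
    for name, pool in pools.items():
        if len(pool) < family_size:
            raise ValueError(
                f"family {name!r} has only {len(pool)} variants < {family_size}"
            )
    for _ in range(max_retries):
        records, labels = [], {}
        for name in family_names:
            pick = rng.choice(len(pools[name]), size=family_size, replace=False)
            for j in sorted(pick):
                cid = f"{name[:3]}{j:03d}"
                records.append(
                    CompoundRecord(
                        id=cid,
                        name=f"{name}-{j}",
                        smiles=pools[name][j],
                        ob=float(rng.uniform(20.0, 80.0)),
                        dl=float(rng.uniform(0.18, 0.95)),
                        source="synthetic",
                    )
                )
                labels[cid] = name
        compounds = CompoundSet(tuple(records))
        got = _library_margin(compounds, labels)
        if n_families == 1 or got >= margin:
            return CompoundLibrary(compounds, labels, got)
    raise RuntimeError(
        f"could not reach Tanimoto margin {margin} in {max_retries} draws"
    )


# ------------------------------------------------------------- activity labels

#: Planted activity-defining substructure (2-substituted furan) and the
#: chain-fragment vocabulary used to grow scaffolds around it.  Every
#: fragment concatenates validly in a linear SMILES.
PLANTED_SUBSTRUCTURE = "c1ccco1"
_CHAIN_FRAGMENTS = ["C", "CC", "CO", "CN", "CCO", "C(C)C", "C(=O)N", "CS", "CCC"]
_INACTIVE_TAILS = ["C1CCCO1", "c1ccccc1", "C1CCCC1", "CC", "CO"]


def gen_activity_dataset(
    seed: int,
    n: int = 1000,
    noise: float = 0.0,
    max_fragments: int = 5,
) -> tuple[ActivityDataset, str]:
    """Labeled SMILES where (pre-noise) active <=> contains a planted furan.

    Scaffolds are random linear chains of 2..max_fragments vocabulary
    fragments; actives end in the planted furan, inactives in a
    non-matching tail.  Classes are balanced to within one record, then
    labels are flipped i.i.d. with probability ``noise``.  Returns the
    dataset and the ground-truth substructure SMARTS.
    """
    if not 0.0 <= noise <= 1.0:
        raise ValueError("noise must be in [0, 1]")
    rng = np.random.default_rng(child_seed(seed, "activity"))
    n_active = n // 2 + n % 2
    n_inactive = n // 2
    records: list[tuple[str, str, int]] = []
    seen: set[str] = set()
    counts = {1: 0, 0: 0}
    goal = {1: n_active, 0: n_inactive}
    guard = 0
    while (counts[1] < goal[1] or counts[0] < goal[0]) and guard < 100 * n:
        guard += 1
        label = 1 if counts[1] < goal[1] else 0
        if counts[0] < goal[0] and counts[1] < goal[1]:
            label = int(rng.integers(0, 2))
        k = int(rng.integers(2, max_fragments + 1))
        chain = "".join(
            _CHAIN_FRAGMENTS[int(i)]
            for i in rng.integers(0, len(_CHAIN_FRAGMENTS), size=k)
        )
        tail = (
            PLANTED_SUBSTRUCTURE
            if label == 1
            else _INACTIVE_TAILS[int(rng.integers(0, len(_INACTIVE_TAILS)))]
        )
        canon = canonical_smiles(chain + tail)
        if canon is None or canon in seen:
            continue
        seen.add(canon)
        records.append((f"m{len(records):05d}", canon, label))
        counts[label] += 1
    if counts[1] < goal[1] or counts[0] < goal[0]:
        raise RuntimeError("could not generate enough unique molecules")
    if noise > 0:
        flip = rng.random(len(records)) < noise
        records = [
            (rid, smi, 1 - lab if f else lab)
            for (rid, smi, lab), f in zip(records, flip)
        ]
    return (
        ActivityDataset(tuple(records), provenance=f"synthetic(seed={seed})"),
        PLANTED_SUBSTRUCTURE,
    )


# ------------------------------------------------------------------- PPI graph

@dataclass(frozen=True)
class PlantedPPI:
    edges: tuple[tuple[str, str, float], ...]
    nodes: tuple[str, ...]
    clique_members: tuple[str, ...]


def gen_ppi_graph(
    seed: int,
    n: int = 60,
    background_p: float = 0.05,
    clique_size: int = 6,
    score_range: tuple[float, float] = (0.4, 1.0),
) -> PlantedPPI:
    """Erdős–Rényi background G(n, p) plus one planted clique of given size.

    Edge confidences are sampled uniformly from ``score_range``.  With
    ``clique_size=0`` no structure is planted; ``n=1`` yields an empty
    edge list.
    """
    if clique_size > n:
        raise ValueError("clique_size cannot exceed n")
    rng = np.random.default_rng(child_seed(seed, "ppi"))
    names = [f"G{i:04d}" for i in range(1, n + 1)]
    g = nx.gnp_random_graph(n, background_p, seed=int(rng.integers(0, 2**31 - 1)))
    clique = sorted(rng.choice(n, size=clique_size, replace=False)) if clique_size else []
    for u, v in itertools.combinations(clique, 2):
        g.add_edge(int(u), int(v))
    edges = tuple(
        (names[u], names[v], float(rng.uniform(*score_range)))
        for u, v in sorted(g.edges())
    )
    return PlantedPPI(
        edges=edges,
        nodes=tuple(names),
        clique_members=tuple(names[i] for i in clique),
    )


# ------------------------------------------------------------------- gene sets

@dataclass(frozen=True)
class PlantedEnrichment:
    annotations: AnnotationCollection
    query: GeneSet
    planted_term: str
    overlap_k: int


def gen_gene_sets(
    seed: int,
    universe_size: int = 1000,
    term_size: int = 50,
    query_size: int = 40,
    overlap_k: int = 10,
    n_distractors: int = 20,
) -> PlantedEnrichment:
    """A gene universe with one planted term overlapping the query at exact k.

    Distractor terms are random draws of the same size from the universe,
    so their query overlaps sit near the null expectation n*K/N.
    """
    if overlap_k > min(term_size, query_size):
        raise ValueError("overlap_k cannot exceed term or query size")
    rng = np.random.default_rng(child_seed(seed, "genesets"))
    universe = [f"G{i:05d}" for i in range(1, universe_size + 1)]
    perm = rng.permutation(universe_size)
    term_idx = perm[:term_size]
    outside_idx = perm[term_size:]
    query_idx = np.concatenate(
        [term_idx[:overlap_k], outside_idx[: query_size - overlap_k]]
    )
    terms: dict[str, tuple[str, list[str]]] = {
        "T0000": ("planted term", [universe[i] for i in term_idx])
    }
    for d in range(1, n_distractors + 1):
        pick = rng.choice(universe_size, size=term_size, replace=False)
        terms[f"T{d:04d}"] = (f"distractor {d}", [universe[i] for i in pick])
    ann = AnnotationCollection.from_terms(terms, universe=universe)
    query = GeneSet.from_symbols("query", [universe[i] for i in query_idx])
    return PlantedEnrichment(ann, query, "T0000", overlap_k)


# ----------------------------------------------------------------- trajectory

@dataclass(frozen=True)
class PlantedTrajectory:
    trajectory: Trajectory
    blocks: tuple[tuple[int, int], ...]
    sigma: tuple[float, ...]
    hinge_amplitude: float
    hinge_sign: int
    expected_between_corr: float


def _backbone(n_atoms: int) -> np.ndarray:
    """A gentle 3-D helix with ~3.8 Å spacing — a protein-like CA trace."""
    t = np.arange(n_atoms) * 0.6
    return np.column_stack([5.0 * np.cos(t), 5.0 * np.sin(t), 1.9 * t])


def gen_trajectory(
    seed: int,
    n_frames: int = 200,
    n_atoms: int = 60,
    blocks: Sequence[tuple[int, int]] = ((0, 30), (30, 60)),
    sigma: Sequence[float] = (0.3, 0.3),
    hinge_amplitude: float = 0.0,
    hinge_sign: int = -1,
    rigid_contamination: bool = False,
) -> PlantedTrajectory:
    """Synthetic CA-trace trajectory with planted fluctuation structure.

    Each atom receives isotropic Gaussian jitter with its block's sigma
    (Å).  A nonzero ``hinge_amplitude`` adds a collective mode: a shared
    scalar time series displaces block 0 along +u and block 1 along
    ``hinge_sign``·u, planting inter-block correlation of magnitude
    amp² / (amp² + σ²) and that sign.  ``rigid_contamination`` composes a
    random rigid rotation+translation onto every frame, which alignment
    must remove.
    """
    if len(blocks) != len(sigma):
        raise ValueError("one sigma per block required")
    rng = np.random.default_rng(child_seed(seed, "trajectory"))
    base = _backbone(n_atoms)
    coords = np.repeat(base[None, :, :], n_frames, axis=0)
    for (lo, hi), s in zip(blocks, sigma):
        if s > 0:
            coords[:, lo:hi, :] += rng.normal(0.0, s, size=(n_frames, hi - lo, 3))
    expected = 0.0
    if hinge_amplitude > 0 and len(blocks) >= 2:
        # The mode displaces the blocks along their separation axis (a
        # stretch/compression), which no rigid rotation can mimic, so
        # superposition cannot absorb it.
        u = np.array([0.0, 0.0, 1.0])
        s_t = rng.normal(0.0, hinge_amplitude, size=n_frames)
        lo0, hi0 = blocks[0]
        lo1, hi1 = blocks[1]
        coords[:, lo0:hi0, :] += s_t[:, None, None] * u
        coords[:, lo1:hi1, :] += hinge_sign * s_t[:, None, None] * u
        # hinge acts on one axis; jitter is isotropic 3-D, so the
        # displacement dot product gives corr = amp^2 / (amp^2 + 3 sigma^2)
        amp2, s2 = hinge_amplitude**2, float(np.mean(np.square(sigma[:2])))
        expected = hinge_sign * amp2 / (amp2 + 3 * s2)
    if rigid_contamination:
        from scipy.spatial.transform import Rotation

        for f in range(n_frames):
            rot = Rotation.random(random_state=int(rng.integers(0, 2**31 - 1)))
            shift = rng.uniform(-20, 20, size=3)
            coords[f] = coords[f] @ rot.as_matrix().T + shift
    traj = Trajectory(coords=coords, atom_names=["CA"] * n_atoms)
    return PlantedTrajectory(
        trajectory=traj,
        blocks=tuple(tuple(b) for b in blocks),
        sigma=tuple(float(s) for s in sigma),
        hinge_amplitude=float(hinge_amplitude),
        hinge_sign=int(hinge_sign),
        expected_between_corr=float(expected),
    )
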