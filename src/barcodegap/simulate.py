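"""Synthetic barcode datasets with known truth.

Generates aligned COI-like datasets with the statistical structure that
stresses distance-based species delimitation: recent radiations whose
interspecific divergences rival intraspecific ones, species complexes
lumped under a single historic label, groups of historic "species" merged
into one current species, hybridising pairs sharing mitochondrial
haplotypes, and post-baseline discoveries (new taxa and new forms of
existing species).

The substitution process is a continuous-time two-parameter model (one
transition rate, one transversion rate, ratio ``kappa``), i.e. exactly the
process the K2P estimator assumes, so the estimator is unbiased on its own
generator.  Genealogies are star approximations: each specimen's lineage
evolves independently for ``intra_depth/2`` from the population's
ancestral sequence, giving expected pairwise intraspecific divergence
``intra_depth``.  Only the distance distributions matter to the downstream
methods, not genealogical fine structure.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Optional

import dendropy
import numpy as np

from .io import SequenceRecord, SequenceSet, TaxonomyMap

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)

#: vertebrate-mitochondrial stop codons, as code triples
_STOPS = {(3, 0, 0), (3, 0, 2), (0, 2, 0), (0, 2, 2)}  # TAA TAG AGA AGG


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class PopulationSpec:
    """One simulated population (a cluster of conspecific specimens).

    A current species may span several populations (e.g. a named species
    plus a later-discovered form of it), and one historic label may span
    several populations of different current species (a lumped complex).
    """

    name: str
    truth_label: str
    n_specimens: int
    intra_depth: float
    historic_label: Optional[str] = None
    discovery_status: str = "known_historic"

    def __post_init__(self) -> None:
        if self.n_specimens < 1:
            raise SimulationError(f"population {self.name!r}: n_specimens >= 1")
        if self.intra_depth < 0:
            raise SimulationError(f"population {self.name!r}: intra_depth >= 0")


@dataclass(frozen=True)
class HybridSpec:
    donor: str       # truth label supplying the mitochondria
    recipient: str   # truth label whose specimens are overwritten
    n_captured: int

    def __post_init__(self) -> None:
        if self.donor == self.recipient:
            raise SimulationError("hybrid donor and recipient must differ")


@dataclass
class SimulationConfig:
    seed: int = 0
    seq_length: int = 650
    kappa: float = 4.0
    populations: list[PopulationSpec] = field(default_factory=list)
    tree_newick: str = ""
    lumping: dict[str, frozenset[str]] = field(default_factory=dict)
    hybrid_spec: list[HybridSpec] = field(default_factory=list)
    exemplar_rule: str = "first_specimen"   # or "random"
    codon_screen: bool = False


def _transition_matrix(kappa: float, d: float) -> np.ndarray:
    """Two-parameter transition probabilities over branch length d.

    Rates normalised so the expected substitutions/site equals d; closed
    form of the K2P process (states ordered A, C, G, T).
    """
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    # per Kimura: with transition rate alpha and transversion rate beta each
    e1 = np.exp(-4.0 * beta * d)
    e2 = np.exp(-2.0 * (alpha + beta) * d)
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    P = np.full((4, 4), p_tv)
    np.fill_diagonal(P, p_same)
    P[0, 2] = P[2, 0] = p_ts  # A<->G
    P[1, 3] = P[3, 1] = p_ts  # C<->T
    return P


def _evolve(codes: np.ndarray, d: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    if d <= 0:
        return codes.copy()
    P = _transition_matrix(kappa, d)
    cum = np.cumsum(P, axis=1)
    u = rng.random(codes.size)
    out = np.empty_like(codes)
    for s in range(4):
        mask = codes == s
        if mask.any():
            out[mask] = np.searchsorted(cum[s], u[mask], side="right")
    return np.clip(out, 0, 3)


def _has_internal_stop(codes: np.ndarray) -> bool:
    L = codes.size - codes.size % 3
    trimmed = codes[:L].reshape(-1, 3)
    for i in range(trimmed.shape[0] - 1):  # final codon may be a stop
        if tuple(trimmed[i]) in _STOPS:
            return True
    return False


def _stop_free_root(L: int, rng: np.random.Generator) -> np.ndarray:
    codes = rng.integers(0, 4, size=L).astype(np.uint8)
    trimmed_len = L - L % 3
    cods = codes[:trimmed_len].reshape(-1, 3)
    for i in range(cods.shape[0] - 1):
        while tuple(cods[i]) in _STOPS:
            cods[i] = rng.integers(0, 4, size=3)
    return codes


def codes_to_str(codes: np.ndarray) -> str:
    return _NT[codes].tobytes().decode("ascii")


def simulate_dataset(cfg: SimulationConfig) -> SequenceSet:
    """Simulate a dataset; returns a SequenceSet with ``current`` and
    ``historic`` taxonomies attached and a ``sim`` attribute holding the
    per-population ancestral sequences (used by :func:`inject_hybrids`).
    """
    if not cfg.populations:
        raise SimulationError("no populations configured")
    names = [p.name for p in cfg.populations]
    if len(set(names)) != len(names):
        raise SimulationError("duplicate population names")
    for h, members in cfg.lumping.items():
        if not members:
            raise SimulationError(f"empty lumping set for {h!r}")
    known_truths = {p.truth_label for p in cfg.populations}
    for h, members in cfg.lumping.items():
        if not set(members) <= known_truths:
            raise SimulationError(
                f"lumping {h!r} references unknown truth labels "
                f"{sorted(set(members) - known_truths)}"
            )

    rng = np.random.default_rng(cfg.seed)
    tree = dendropy.Tree.get(data=cfg.tree_newick, schema="newick")
    tip_names = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if tip_names != set(names):
        raise SimulationError(
            "tree tips and population names differ: "
            f"{sorted(tip_names ^ set(names))}"
        )

    if cfg.codon_screen:
        root_codes = _stop_free_root(cfg.seq_length, rng)
    else:
        root_codes = rng.integers(0, 4, size=cfg.seq_length).astype(np.uint8)

    def evolve_branch(parent_seq: np.ndarray, d: float, what: str) -> np.ndarray:
        # with the codon screen on, mutations creating internal stops are
        # resampled (redraw the branch until the child sequence is clean)
        for _attempt in range(60):
            child = _evolve(parent_seq, d, cfg.kappa, rng)
            if not (cfg.codon_screen and _has_internal_stop(child)):
                return child
        raise SimulationError(f"could not draw stop-free sequence for {what}")

    # evolve the species tree (preorder), then the star genealogies
    anc: dict[str, np.ndarray] = {}
    node_seq = {tree.seed_node: root_codes}
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        parent_seq = node_seq[nd.parent_node]
        d = nd.edge.length or 0.0
        node_seq[nd] = evolve_branch(parent_seq, d, "internal branch")
        if nd.is_leaf():
            anc[nd.taxon.label] = node_seq[nd]

    records: list[SequenceRecord] = []
    pop_of: dict[str, str] = {}
    for pop in cfg.populations:
        for k in range(pop.n_specimens):
            sid = f"{pop.name}_{k + 1:02d}"
            codes = evolve_branch(anc[pop.name], pop.intra_depth / 2.0, sid)
            records.append(SequenceRecord(sid, codes_to_str(codes)))
            pop_of[sid] = pop.name

    pop_by_name = {p.name: p for p in cfg.populations}
    current = TaxonomyMap(scheme_name="current")
    historic = TaxonomyMap(scheme_name="historic")
    for r in records:
        pop = pop_by_name[pop_of[r.specimen_id]]
        current.label_of[r.specimen_id] = pop.truth_label
        current.discovery_status_of[r.specimen_id] = pop.discovery_status
        if pop.historic_label is not None:
            historic.label_of[r.specimen_id] = pop.historic_label
            historic.discovery_status_of[r.specimen_id] = pop.discovery_status

    def designate(tax: TaxonomyMap) -> None:
        by_species: dict[str, list[str]] = {}
        for sid in (r.specimen_id for r in records):
            lab = tax.label_of.get(sid)
            if lab is not None:
                by_species.setdefault(lab, []).append(sid)
        for lab, sids in by_species.items():
            # prefer a specimen of a known-historic population where one exists
            known = [
                s for s in sids
                if pop_by_name[pop_of[s]].discovery_status == "known_historic"
            ]
            candidates = known or sids
            if cfg.exemplar_rule == "random":
                tax.exemplar_of[lab] = candidates[rng.integers(len(candidates))]
            else:
                tax.exemplar_of[lab] = candidates[0]

    designate(current)
    designate(historic)

    # lumping map lives on the historic scheme; derive implicit entries
    derived: dict[str, set[str]] = {}
    for pop in cfg.populations:
        if pop.historic_label is not None:
            derived.setdefault(pop.historic_label, set()).add(pop.truth_label)
    for h, members in cfg.lumping.items():
        derived.setdefault(h, set()).update(members)
    historic.complex_map = {
        h: frozenset(mem) for h, mem in derived.items() if len(mem) >= 2
    }

    sset = SequenceSet(records, cfg.seq_length, {"current": current, "historic": historic})
    sset.sim = {
        "populations": {
            p.name: {"ancestral": anc[p.name], "spec": p} for p in cfg.populations
        },
        "pop_of": pop_of,
        "kappa": cfg.kappa,
        "captured": [],
    }
    for hs in cfg.hybrid_spec:
        sset = inject_hybrids(
            sset, current, hs.donor, hs.recipient, hs.n_captured,
            seed=int(rng.integers(2**31)),
        )
    return sset


def inject_hybrids(
    sset: SequenceSet,
    truth_tax: TaxonomyMap,
    donor: str,
    recipient: str,
    k: int,
    seed: int = 0,
) -> SequenceSet:
    """Model mtDNA capture: k recipient specimens get fresh donor haplotypes.

    Replaced specimens keep their ids and labels; their sequences are new
    draws from the donor population's intraspecific process.  Requires the
    simulator bookkeeping attached by :func:`simulate_dataset`.
    """
    sim = getattr(sset, "sim", None)
    if sim is None:
        raise SimulationError("inject_hybrids needs a simulated SequenceSet")
    recip_ids = [s for s, l in truth_tax.label_of.items() if l == recipient]
    if not recip_ids:
        raise SimulationError(f"unknown recipient species {recipient!r}")
    donor_pops = [
        info for info in sim["populations"].values()
        if info["spec"].truth_label == donor
    ]
    if not donor_pops:
        raise SimulationError(f"unknown donor species {donor!r}")
    if k > len(recip_ids):
        raise SimulationError(
            f"cannot capture {k} of {len(recip_ids)} recipient specimens"
        )
    if k == 0:
        return sset
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(sorted(recip_ids), size=k, replace=False))
    donor_info = donor_pops[0]
    depth = donor_info["spec"].intra_depth / 2.0
    new_records = []
    for r in sset.records:
        if r.specimen_id in chosen:
            codes = _evolve(donor_info["ancestral"], depth, sim["kappa"], rng)
            new_records.append(SequenceRecord(r.specimen_id, codes_to_str(codes)))
        else:
            new_records.append(r)
    out = SequenceSet(new_records, sset.aligned_length, sset.taxonomies)
    out.sim = copy.copy(sim)
    out.sim["captured"] = list(sim["captured"]) + list(chosen)
    return out


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _gapped_config(seed: int = 0) -> SimulationConfig:
    """Clean global gap: 20 species x 5 specimens, ~2% intra, ~10% inter."""
    names = [f"sp{i:02d}" for i in range(1, 21)]
    pops = [
        PopulationSpec(n, truth_label=n, historic_label=n, n_specimens=5,
                       intra_depth=0.02)
        for n in names
    ]
    tree = "(" + ",".join(f"{n}:0.05" for n in names) + ");"
    return SimulationConfig(seed=seed, populations=pops, tree_newick=tree)


def _skink_world(seed: int = 0) -> SimulationConfig:
    """A radiation shaped like the New Zealand skink dataset.

    23 historic labels; a 6-species recent radiation (~1.2% between
    species), four historic labels merged into one current species, three
    lumped complexes split since (one with a third, newly discovered
    member), a hybridising pair with two captured mitochondria, eight
    well-separated species with sizes 1-20 including singletons, plus two
    new taxa and two new forms discovered after the baseline.
    """
    pops: list[PopulationSpec] = []
    for i in range(1, 7):
        pops.append(PopulationSpec(f"r{i}", f"r{i}", 12, 0.003, f"r{i}"))
    for i in range(1, 5):
        pops.append(PopulationSpec(f"m{i}", "m_all", 12, 0.003, f"m{i}"))
    pops += [
        PopulationSpec("c1a", "c1a", 6, 0.01, "c1"),
        PopulationSpec("c1b", "c1b", 6, 0.01, "c1"),
        PopulationSpec("c1c", "c1c", 4, 0.003, None, "new_taxon"),
        PopulationSpec("c2a", "c2a", 6, 0.01, "c2"),
        PopulationSpec("c2b", "c2b", 6, 0.01, "c2"),
        PopulationSpec("c3a", "c3a", 6, 0.01, "c3"),
        PopulationSpec("c3b", "c3b", 6, 0.01, "c3"),
        PopulationSpec("hd", "hd", 12, 0.006, "hd"),
        PopulationSpec("hr", "hr", 8, 0.006, "hr"),
    ]
    n_sizes = [1, 1, 2, 3, 5, 8, 12, 20]
    n_intra = [0.004, 0.004, 0.01, 0.01, 0.015, 0.015, 0.02, 0.02]
    for i, (size, depth) in enumerate(zip(n_sizes, n_intra), start=1):
        pops.append(PopulationSpec(f"n{i}", f"n{i}", size, depth, f"n{i}"))
    pops += [
        PopulationSpec("nf1", "n8", 4, 0.003, None, "new_form_of_existing"),
        PopulationSpec("nf2", "n7", 4, 0.003, None, "new_form_of_existing"),
        PopulationSpec("x2", "x2", 3, 0.003, None, "new_taxon"),
        PopulationSpec("x3", "x3", 3, 0.003, None, "new_taxon"),
    ]
    # depths chosen so that within-complex divergence (~12%) rivals the
    # between-group distances (~10-13%): under the historic labels the
    # intra- and inter-specific distance distributions then overlap almost
    # completely, as in a recent radiation with unrecognised complexes
    rad = ",".join(f"r{i}:0.006" for i in range(1, 7))
    mrg = ",".join(f"m{i}:0.005" for i in range(1, 5))
    tree = (
        "("
        f"(({rad}):0.025,x3:0.05):0.035,"
        f"({mrg}):0.055,"
        "((c1a:0.04,c1c:0.04):0.04,c1b:0.08):0.005,"
        "(c2a:0.08,c2b:0.08):0.005,"
        "(c3a:0.08,c3b:0.08):0.005,"
        "(hd:0.03,hr:0.03):0.045,"
        "((n1:0.03,n2:0.03,n3:0.03,n4:0.03):0.02,"
        "(n5:0.03,n6:0.03,(n7:0.0025,nf2:0.0025):0.0275,"
        "(n8:0.0025,nf1:0.0025):0.0275):0.02,x2:0.03):0.025"
        ");"
    )
    lumping = {
        "c1": frozenset({"c1a", "c1b", "c1c"}),
        "c2": frozenset({"c2a", "c2b"}),
        "c3": frozenset({"c3a", "c3b"}),
    }
    return SimulationConfig(
        seed=seed,
        populations=pops,
        tree_newick=tree,
        lumping=lumping,
        hybrid_spec=[HybridSpec("hd", "hr", 2)],
    )


def _skink_1977_config(seed: int = 0) -> SimulationConfig:
    """The historic-baseline subset: only populations known at the baseline."""
    world = _skink_world(seed)
    pops = [p for p in world.populations if p.historic_label is not None]
    names = {p.name for p in pops}
    truths = {p.truth_label for p in pops}
    world.lumping = {
        h: frozenset(mem & truths)
        for h, mem in world.lumping.items()
        if mem & truths
    }
    tree = dendropy.Tree.get(data=world.tree_newick, schema="newick")
    tree.retain_taxa_with_labels(sorted(names))
    newick = tree.as_string(schema="newick").strip()
    return replace(world, populations=pops, tree_newick=newick)


def presets(seed: int = 0) -> dict[str, SimulationConfig]:
    """Named study conditions: ``gapped``, ``skink1977``, ``skink_current``."""
    return {
        "gapped": _gapped_config(seed),
        "skink1977": _skink_1977_config(seed),
        "skink_current": _skink_world(seed),
    }


def get_preset(name: str, seed: int = 0) -> SimulationConfig:
    all_presets = presets(seed)
    if name not in all_presets:
        raise SimulationError(
            f"unknown preset {name!r}; available: {sorted(all_presets)}"
        )
    return all_presets[name]
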