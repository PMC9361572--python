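"""Synthetic-data generators with exact planted ground truth.

Three generators mirror the three inputs the pipeline consumes:

* :func:`simulate_codon_pair` — an aligned codon pair diverged to a
  target Ks at a chosen dN/dS ratio, with realized substitution counts
  as ground truth;
* :func:`simulate_genome` — gene loci with planted tandem arrays,
  proximal pairs, dispersed pairs and collinear blocks, with true
  duplication-type labels;
* :func:`simulate_gene_tree` — a gene tree grown from a species tree by
  explicit duplication and loss events, with planted event counts.

All generators are pure functions of their spec (including the seed).
Divergence in the codon simulator is controlled by counting realized
accepted synonymous events against the ancestor's NG86 synonymous site
count, so recovery tests have exact ground truth without solving for
expected substitutions under rejection sampling.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .classify import DupClass
from .io_formats import GeneLocus, GenePairList, make_pair_list, read_newick
from .ng86 import (
    GENETIC_CODE,
    NUCLEOTIDES,
    STOP_CODONS,
    AlignedCodonPair,
    count_codon_sites,
)

SENSE_CODONS = tuple(sorted(GENETIC_CODE))


# ---------------------------------------------------------------------------
# codon pair simulation


@dataclass(frozen=True)
class PairSimSpec:
    """Parameters for one simulated aligned codon pair."""

    n_codons: int = 300
    target_ks: float = 0.3
    omega: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if self.target_ks < 0:
            raise ValueError("target_ks must be >= 0")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")


def _mutate_lineage(codons: list[str], target_syn: int, omega: float, rng) -> dict:
    """Evolve one lineage until `target_syn` synonymous events accepted.

    Proposals are uniform over sites and alternative bases; proposals
    creating stop codons are rejected outright; nonsynonymous proposals
    are accepted with probability omega, synonymous ones always.
    """
    syn = nonsyn = 0
    n_sites = 3 * len(codons)
    while syn < target_syn:
        site = rng.randrange(n_sites)
        ci, pos = divmod(site, 3)
        cur = codons[ci]
        base = rng.choice([b for b in NUCLEOTIDES if b != cur[pos]])
        mutant = cur[:pos] + base + cur[pos + 1 :]
        if mutant in STOP_CODONS:
            continue
        if GENETIC_CODE[mutant] == GENETIC_CODE[cur]:
            codons[ci] = mutant
            syn += 1
        elif rng.random() < omega:
            codons[ci] = mutant
            nonsyn += 1
    return {"syn_events": syn, "nonsyn_events": nonsyn}


def simulate_codon_pair(spec: PairSimSpec) -> tuple[AlignedCodonPair, dict]:
    """Simulate a pair of coding sequences diverged to a target Ks.

    A uniform-random ancestor of sense codons evolves down two
    independent lineages; each lineage accumulates accepted synonymous
    events until their count per ancestral NG86 synonymous site reaches
    target_ks / 2.  Returns the aligned pair plus ground truth (ancestor
    site counts and realized per-lineage event counts).
    """
    rng = random.Random(spec.seed)
    ancestor = [rng.choice(SENSE_CODONS) for _ in range(spec.n_codons)]
    s_anc = sum(count_codon_sites(c).S for c in ancestor)
    target_syn = round(spec.target_ks / 2.0 * s_anc)
    if spec.target_ks > 0 and s_anc == 0:
        raise ValueError(
            "ancestor has zero synonymous sites; cannot reach target_ks > 0"
        )

    lineages = []
    truth_lineages = []
    for _ in range(2):
        codons = list(ancestor)
        truth_lineages.append(_mutate_lineage(codons, target_syn, spec.omega, rng))
        lineages.append("".join(codons))

    pair = AlignedCodonPair(f"sim_ks{spec.target_ks}_seed{spec.seed}", *lineages)
    truth = {
        "ancestor_S": s_anc,
        "ancestor_N": 3.0 * spec.n_codons - s_anc,
        "target_syn_events_per_lineage": target_syn,
        "lineages": truth_lineages,
        "total_syn_events": sum(l["syn_events"] for l in truth_lineages),
        "total_nonsyn_events": sum(l["nonsyn_events"] for l in truth_lineages),
    }
    return pair, truth


# ---------------------------------------------------------------------------
# genome simulation


@dataclass(frozen=True)
class GenomeSimSpec:
    """Layout of a synthetic genome with planted duplication structure."""

    n_chromosomes: int = 5
    genes_per_chromosome: int = 40
    n_tandem_arrays: int = 3
    n_proximal_pairs: int = 3
    n_collinear_blocks: int = 2
    block_length: int = 5
    n_dispersed_pairs: int = 2
    tandem_array_size: int = 2
    proximal_window: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.genes_per_chromosome < 1:
            raise ValueError("genome must have at least one chromosome and gene")
        for name in (
            "n_tandem_arrays",
            "n_proximal_pairs",
            "n_collinear_blocks",
            "n_dispersed_pairs",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.block_length < 1 or self.tandem_array_size < 2:
            raise ValueError("block_length >= 1 and tandem_array_size >= 2 required")
        if self.proximal_window < 2:
            raise ValueError("proximal_window must be >= 2")
        if self.n_collinear_blocks > 0 and self.n_chromosomes < 2:
            raise ValueError("collinear blocks need at least two chromosomes")


_GENE_SPACING = 1000
_GENE_LENGTH = 500
_MAX_PLACEMENT_TRIES = 500


class _Layout:
    """Free-slot bookkeeping for feature placement on chromosomes."""

    def __init__(self, spec: GenomeSimSpec):
        self.spec = spec
        self.free = {
            c: [True] * spec.genes_per_chromosome for c in range(spec.n_chromosomes)
        }

    def take_run(self, rng, length: int, exclude: int | None = None) -> tuple[int, int]:
        """Claim `length` consecutive free ranks on a random chromosome."""
        chroms = [c for c in range(self.spec.n_chromosomes) if c != exclude]
        if length > self.spec.genes_per_chromosome or not chroms:
            raise ValueError("could not place feature: genome capacity exceeded")
        for _ in range(_MAX_PLACEMENT_TRIES):
            c = rng.choice(chroms)
            start = rng.randrange(self.spec.genes_per_chromosome - length + 1)
            if all(self.free[c][start : start + length]):
                for r in range(start, start + length):
                    self.free[c][r] = False
                return c, start
        raise ValueError("could not place feature: genome capacity exceeded")

    def take_gap_pair(self, rng, gap: int) -> tuple[int, int, int]:
        """Claim two free ranks `gap` apart on one chromosome."""
        for _ in range(_MAX_PLACEMENT_TRIES):
            c = rng.randrange(self.spec.n_chromosomes)
            if self.spec.genes_per_chromosome <= gap:
                break
            start = rng.randrange(self.spec.genes_per_chromosome - gap)
            if self.free[c][start] and self.free[c][start + gap]:
                self.free[c][start] = self.free[c][start + gap] = False
                return c, start, start + gap
        raise ValueError("could not place feature: genome capacity exceeded")

    def take_single(self, rng, exclude_chrom: int | None = None) -> tuple[int, int]:
        for _ in range(_MAX_PLACEMENT_TRIES):
            c = rng.randrange(self.spec.n_chromosomes)
            if c == exclude_chrom:
                continue
            r = rng.randrange(self.spec.genes_per_chromosome)
            if self.free[c][r]:
                self.free[c][r] = False
                return c, r
        raise ValueError("could not place feature: genome capacity exceeded")


def _gene_id(chrom: int, rank: int) -> str:
    return f"chr{chrom + 1}_g{rank:03d}"


def simulate_genome(
    spec: GenomeSimSpec,
) -> tuple[list[GeneLocus], GenePairList, GenePairList, dict[str, DupClass]]:
    """Generate loci, homolog pairs, collinear pairs and true labels.

    Planted features occupy disjoint gene slots: collinear blocks are
    rank-preserving homolog runs across two chromosomes, tandem arrays
    are adjacent homolog runs, proximal pairs sit 2..window ranks apart,
    dispersed pairs span different chromosomes.  All other genes are
    singletons.  Collinear pairs are also listed as homologs, as a real
    homology table would.
    """
    rng = random.Random(spec.seed)
    layout = _Layout(spec)
    homologs: list[tuple[str, str]] = []
    collinear: list[tuple[str, str]] = []
    truth: dict[str, DupClass] = {}

    for _ in range(spec.n_collinear_blocks):
        c1, s1 = layout.take_run(rng, spec.block_length)
        c2, s2 = layout.take_run(rng, spec.block_length, exclude=c1)
        for k in range(spec.block_length):
            a, b = _gene_id(c1, s1 + k), _gene_id(c2, s2 + k)
            collinear.append((a, b))
            homologs.append((a, b))
            truth[a] = truth[b] = DupClass.WGD_SEGMENTAL

    for _ in range(spec.n_tandem_arrays):
        c, s = layout.take_run(rng, spec.tandem_array_size)
        members = [_gene_id(c, s + k) for k in range(spec.tandem_array_size)]
        for a, b in zip(members, members[1:]):
            homologs.append((a, b))
        for g in members:
            truth[g] = DupClass.TANDEM

    for _ in range(spec.n_proximal_pairs):
        gap = rng.randint(2, spec.proximal_window)
        c, r1, r2 = layout.take_gap_pair(rng, gap)
        a, b = _gene_id(c, r1), _gene_id(c, r2)
        homologs.append((a, b))
        truth[a] = truth[b] = DupClass.PROXIMAL

    for _ in range(spec.n_dispersed_pairs):
        c1, r1 = layout.take_single(rng)
        c2, r2 = layout.take_single(rng, exclude_chrom=c1)
        a, b = _gene_id(c1, r1), _gene_id(c2, r2)
        homologs.append((a, b))
        truth[a] = truth[b] = DupClass.DISPERSED

    loci: list[GeneLocus] = []
    for c in range(spec.n_chromosomes):
        for r in range(spec.genes_per_chromosome):
            gid = _gene_id(c, r)
            start = r * _GENE_SPACING
            loci.append(
                GeneLocus(
                    gid,
                    f"chr{c + 1}",
                    start,
                    start + _GENE_LENGTH,
                    rng.choice("+-"),
                    rank=r,
                )
            )
            truth.setdefault(gid, DupClass.SINGLETON)

    return (
        loci,
        make_pair_list(homologs, "homolog"),
        make_pair_list(collinear, "collinear"),
        truth,
    )


# ---------------------------------------------------------------------------
# gene tree simulation


@dataclass
class _GN:
    """A gene-lineage node during top-down growth."""

    kind: str = "open"  # open | dup | spec | leaf | lost
    children: list = field(default_factory=list)
    branch_key: str | None = None
    name: str | None = None

    def surviving_leaves(self) -> list["_GN"]:
        if self.kind == "leaf":
            return [self]
        if self.kind == "lost":
            return []
        out: list[_GN] = []
        for c in self.children:
            out.extend(c.surviving_leaves())
        return out


def species_branch_key(node) -> str:
    """Key identifying the branch above a species-tree node."""
    if node.is_leaf():
        return node.taxon.label
    if node.label:
        return node.label
    return "|".join(sorted(l.taxon.label for l in node.leaf_iter()))


def _newick(node: _GN) -> str | None:
    if node.kind == "lost":
        return None
    if node.kind == "leaf":
        return node.name
    parts = [s for s in (_newick(c) for c in node.children) if s is not None]
    if not parts:
        return None
    if len(parts) == 1:
        return parts[0]  # contract unary nodes
    return "(" + ",".join(parts) + ")"


def simulate_gene_tree(
    species_tree, events: list[tuple[str, str]], seed: int = 0
) -> tuple:
    """Grow a gene tree from a species tree by explicit events.

    ``events`` is a list of (branch_key, "duplication"|"loss") where the
    branch key is the species node label (leaf label, internal label, or
    sorted leaf labels joined with ``|``).  Events on the same branch
    apply in list order to a random live lineage.  Returns
    (gene_tree, leaf_species_map, truth_counts); truth counts the
    planted events (a duplication both of whose copies die leaves no
    trace and is not counted).

    Raises if a loss empties the whole gene tree or targets a branch
    with no live lineage.
    """
    rng = random.Random(seed)
    branch_keys = {species_branch_key(n) for n in species_tree.preorder_node_iter()}
    by_branch: dict[str, list[str]] = {}
    for branch, ev in events:
        if branch not in branch_keys:
            raise KeyError(f"unknown species branch {branch!r}")
        if ev not in ("duplication", "loss"):
            raise ValueError(f"unknown event type {ev!r}")
        by_branch.setdefault(branch, []).append(ev)

    leaf_counter: dict[str, int] = {}
    planted_dups: list[tuple[str, _GN]] = []
    planted_losses: list[tuple[str, _GN]] = []

    def process(sp_node, entering: list[_GN]) -> None:
        key = species_branch_key(sp_node)
        live = list(entering)
        for ev in by_branch.get(key, []):
            if not live:
                raise ValueError(f"{ev} on branch {key!r} with no live gene lineage")
            target = rng.choice(live)
            live.remove(target)
            target.branch_key = key
            if ev == "duplication":
                target.kind = "dup"
                target.children = [_GN(), _GN()]
                live.extend(target.children)
                planted_dups.append((key, target))
            else:
                target.kind = "lost"
                planted_losses.append((key, target))
        if sp_node.is_leaf():
            label = sp_node.taxon.label
            for copy in live:
                leaf_counter[label] = leaf_counter.get(label, 0) + 1
                copy.kind = "leaf"
                copy.name = f"{label}_{leaf_counter[label]}"
                copy.branch_key = key
        else:
            per_child: list[list[_GN]] = [[] for _ in sp_node.child_nodes()]
            for copy in live:
                copy.kind = "spec"
                copy.branch_key = key
                copy.children = [_GN() for _ in sp_node.child_nodes()]
                for slot, child_gn in zip(per_child, copy.children):
                    slot.append(child_gn)
            for sp_child, entering_child in zip(sp_node.child_nodes(), per_child):
                process(sp_child, entering_child)

    root_copy = _GN()
    process(species_tree.seed_node, [root_copy])

    newick = _newick(root_copy)
    if newick is None:
        raise ValueError("loss events emptied the gene tree")
    gene_tree = read_newick(newick + ";")
    leaf_species_map = {
        leaf.name: leaf.name.rsplit("_", 1)[0] for leaf in root_copy.surviving_leaves()
    }

    dup_by_branch: dict[str, int] = {}
    visible_dups = 0
    for key, gn in planted_dups:
        if all(c.surviving_leaves() for c in gn.children):
            visible_dups += 1
            dup_by_branch[key] = dup_by_branch.get(key, 0) + 1
    loss_by_branch: dict[str, int] = {}
    for key, _gn in planted_losses:
        loss_by_branch[key] = loss_by_branch.get(key, 0) + 1
    truth_counts = {
        "duplications": visible_dups,
        "losses": len(planted_losses),
        "duplications_by_branch": dup_by_branch,
        "losses_by_branch": loss_by_branch,
        "_internal": (root_copy, planted_dups, planted_losses),
    }
    return gene_tree, leaf_species_map, truth_counts


# ---------------------------------------------------------------------------
# guaranteed-observable reconciliation cases


def _species_lca_key(species_tree, species_set: set[str]) -> str:
    """Branch key of the smallest species clade containing `species_set`."""
    best = None
    best_size = None
    for node in species_tree.preorder_node_iter():
        leafset = {l.taxon.label for l in node.leaf_iter()}
        if species_set <= leafset and (best_size is None or len(leafset) < best_size):
            best, best_size = node, len(leafset)
    return species_branch_key(best)


def _leaf_species(gn: _GN) -> set[str]:
    return {leaf.name.rsplit("_", 1)[0] for leaf in gn.surviving_leaves()}


def _observable(root_copy: _GN, planted_dups, planted_losses, species_tree) -> bool:
    """Structural check that LCA parsimony can see every planted event.

    Sufficient conditions (losses restricted to terminal branches):
    every duplication keeps survivors on both sides and at least one
    copy's surviving species still span the duplication branch (copies
    surviving in disjoint sub-clades masquerade as a speciation); any
    speciation side with no survivors died by a direct loss on a
    terminal branch; and no planted loss sits above the first branching
    point of the surviving gene tree (stem losses are invisible).
    """
    for key, gn in planted_dups:
        if not all(c.surviving_leaves() for c in gn.children):
            return False
        if not any(
            _species_lca_key(species_tree, _leaf_species(c)) == key
            for c in gn.children
        ):
            return False
    leaf_labels = {l.taxon.label for l in species_tree.leaf_node_iter()}

    def check(gn: _GN) -> bool:
        if gn.kind in ("leaf", "lost"):
            return True
        if gn.kind == "spec":
            for c in gn.children:
                if not c.surviving_leaves():
                    # dead side must be a single direct loss on a leaf branch
                    if not (c.kind == "lost" and c.branch_key in leaf_labels):
                        return False
        return all(check(c) for c in gn.children)

    if not check(root_copy):
        return False

    # no losses on the unary chain above the gene-tree root
    node = root_copy
    while True:
        if node.kind in ("leaf", "lost"):
            break
        alive = [c for c in node.children if c.surviving_leaves()]
        if len(alive) >= 2:
            break
        for c in node.children:
            if not c.surviving_leaves():
                return False  # a loss (or dead subtree) above the gene root
        node = alive[0]
    return True


def simulate_reconciliation_case(
    species_tree, n_duplications: int, n_losses: int, seed: int = 0
) -> tuple:
    """A random reconciliation test case with fully observable truth.

    Duplications are planted on random branches and losses on random
    terminal branches; configurations whose planted history parsimony
    cannot recover (hidden or collapsed events) are rejected and
    redrawn deterministically from the seed.  Returns
    (gene_tree, leaf_species_map, truth_counts).
    """
    internal = [
        species_branch_key(n)
        for n in species_tree.preorder_node_iter()
    ]
    leaves = [l.taxon.label for l in species_tree.leaf_node_iter()]
    for attempt in range(2000):
        sub = random.Random((seed * 100003 + attempt) & 0x7FFFFFFF)
        events = [(sub.choice(internal), "duplication") for _ in range(n_duplications)]
        loss_leaves = sub.sample(leaves, k=min(n_losses, len(leaves)))
        events += [(leaf, "loss") for leaf in loss_leaves]
        try:
            gene_tree, leaf_map, truth = simulate_gene_tree(
                species_tree, events, seed=seed + 7919 * attempt
            )
        except ValueError:
            continue
        root_copy, pd, pl = truth["_internal"]
        if truth["duplications"] != n_duplications or truth["losses"] != n_losses:
            continue
        if _observable(root_copy, pd, pl, species_tree):
            truth = {k: v for k, v in truth.items() if k != "_internal"}
            return gene_tree, leaf_map, truth
    raise RuntimeError("could not generate an observable reconciliation case")
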