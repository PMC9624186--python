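"""Recursive per-cluster admixture re-analysis ("hierarchical" clustering).

Top level: scan K over 1..min(K_max, n_pops + slack) with replicate runs,
build the Evanno table, pick K* by delta-K, split individuals by their
argmax-q cluster, and recurse into each retained cluster until a subset can
no longer be divided.  Terminal nodes are the dataset's "genetic
components".

Termination at a node fires when ANY of these holds:

* the subset is smaller than ``min_individuals``;
* the maximum recursion depth is reached;
* the posterior Q is near-symmetric (mean over individuals of max q below
  ``q_threshold``) — the signature of no real structure;
* delta-K selection fails (e.g. zero replicate s.d. everywhere);
* every proposed child equals the parent subset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .admixture_mcmc import MCMCConfig, StructureRun, run_mcmc
from .genotype_data import GenotypeMatrix, subset
from .model_selection import KSelectionTable, SelectionError, build_table, select_optimal_k


@dataclass
class HierConfig:
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    runs_per_k: int = 5
    k_max: int = 12
    k_slack: int = 3
    min_individuals: int = 10
    min_cluster_size: int = 5
    q_threshold: float = 0.6
    max_depth: int = 8
    assign_mode: str = "individual"  # or "population"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.runs_per_k < 2:
            raise ValueError("runs_per_k must be >= 2 (replicate s.d. needed)")
        if self.assign_mode not in ("individual", "population"):
            raise ValueError("assign_mode must be 'individual' or 'population'")


@dataclass
class HierarchyNode:
    indices: np.ndarray                  # global individual indices in this subset
    pops: list[str]
    depth: int
    table: "KSelectionTable | None" = None
    chosen_k: "int | None" = None
    best_run: "StructureRun | None" = None
    children: list["HierarchyNode"] = field(default_factory=list)
    unassigned: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    terminal: bool = False
    reason: "str | None" = None
    component: "int | None" = None

    def walk(self):
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def terminal_nodes(self) -> list["HierarchyNode"]:
        return [n for n in self.walk() if n.terminal]

    def to_dict(self) -> dict:
        table = None
        if self.table is not None:
            def num(v):
                if v is None:
                    return None
                return "inf" if v == float("inf") else v

            table = {
                str(k): {
                    "mean_lnpd": self.table.mean_lnpd[k],
                    "sd_lnpd": self.table.sd_lnpd[k],
                    "delta_k": num(self.table.delta_k.get(k)),
                }
                for k in self.table.ks
            }
        return {
            "depth": self.depth,
            "n_individuals": int(self.indices.size),
            "populations": self.pops,
            "chosen_k": self.chosen_k,
            "k_table": table,
            "terminal": self.terminal,
            "reason": self.reason,
            "component": self.component,
            "n_unassigned": int(self.unassigned.size),
            "children": [c.to_dict() for c in self.children],
        }


def run_level(
    g_subset: GenotypeMatrix, cfg: HierConfig, seed: "int | None" = None
) -> tuple[KSelectionTable, dict[int, list[StructureRun]]]:
    """Scan K over 1..min(k_max, n_pops + k_slack) with replicate runs."""
    if g_subset.n_individuals < cfg.min_individuals:
        raise ValueError("subset smaller than min_individuals")
    n_pops = len(g_subset.populations)
    k_hi = max(3, min(cfg.k_max, n_pops + cfg.k_slack))
    ss = np.random.SeedSequence(seed if seed is not None else cfg.seed)
    runs_by_k: dict[int, list[StructureRun]] = {}
    child_seeds = ss.generate_state(k_hi * cfg.runs_per_k)
    s = 0
    for k in range(1, k_hi + 1):
        runs_by_k[k] = []
        for _ in range(cfg.runs_per_k):
            mc = replace(cfg.mcmc, K=k, seed=int(child_seeds[s]))
            s += 1
            runs_by_k[k].append(run_mcmc(g_subset, mc))
    table = build_table(runs_by_k)
    return table, runs_by_k


def best_run_at(runs_by_k: dict[int, list[StructureRun]], k: int) -> StructureRun:
    """Highest-lnPD replicate at the selected K."""
    return max(runs_by_k[k], key=lambda r: r.lnPD)


def partition_by_assignment(
    indices: np.ndarray,
    Q: np.ndarray,
    min_cluster_size: int = 5,
    pop_labels: "list[str] | None" = None,
    mode: str = "individual",
) -> tuple[list[np.ndarray], np.ndarray]:
    """Split a subset's individuals into argmax-q clusters.

    Returns (child index arrays, unassigned index array).  Clusters smaller
    than ``min_cluster_size`` are dissolved and their members marked
    unassigned.  Ties go to the lowest cluster index (np.argmax convention).
    In ``population`` mode each whole population goes to the majority vote of
    its individuals' argmax clusters.
    """
    K = Q.shape[1]
    assign = np.argmax(Q, axis=1)
    if mode == "population":
        if pop_labels is None:
            raise ValueError("population mode needs pop_labels")
        labels = np.asarray(pop_labels, dtype=object)
        for pop in dict.fromkeys(pop_labels):
            rows = np.flatnonzero(labels == pop)
            votes = np.bincount(assign[rows], minlength=K)
            assign[rows] = int(np.argmax(votes))
    children: list[np.ndarray] = []
    unassigned = []
    for k in range(K):
        members = np.flatnonzero(assign == k)
        if members.size == 0:
            continue
        if members.size < min_cluster_size:
            unassigned.append(members)
        else:
            children.append(indices[members])
    un = np.concatenate(unassigned) if unassigned else np.array([], dtype=int)
    return children, indices[un] if un.size else np.array([], dtype=int)


def mean_max_q(Q: np.ndarray) -> float:
    return float(Q.max(axis=1).mean())


def should_terminate(
    node: HierarchyNode,
    cfg: HierConfig,
    Q: "np.ndarray | None" = None,
    selection_failed: bool = False,
    children: "list[np.ndarray] | None" = None,
) -> "str | None":
    """Return a termination reason, or None to keep dividing."""
    if node.indices.size < cfg.min_individuals:
        return "too_few_individuals"
    if node.depth >= cfg.max_depth:
        return "max_depth"
    if selection_failed:
        return "selection_failure"
    if Q is not None and mean_max_q(Q) < cfg.q_threshold:
        return "symmetric_q"
    if children is not None:
        if not children:
            return "all_clusters_dissolved"
        if any(c.size == node.indices.size for c in children):
            return "child_equals_parent"
    return None


def run_hierarchical(g: GenotypeMatrix, cfg: HierConfig) -> HierarchyNode:
    """Depth-first recursive analysis; terminal nodes get component labels."""
    ss = np.random.SeedSequence(cfg.seed)
    counter = {"component": 0, "node": 0}

    def analyze(indices: np.ndarray, depth: int) -> HierarchyNode:
        sub = subset(g, [int(i) for i in indices])
        node = HierarchyNode(indices=indices, pops=sub.populations, depth=depth)
        reason = should_terminate(node, cfg)
        if reason:
            _finish(node, reason)
            return node
        counter["node"] += 1
        level_seed = int(ss.generate_state(1)[0]) + counter["node"]
        try:
            table, runs_by_k = run_level(sub, cfg, seed=level_seed)
        except ValueError:
            _finish(node, "too_few_individuals")
            return node
        node.table = table
        try:
            k_star = select_optimal_k(table)
        except SelectionError:
            _finish(node, "selection_failure")
            return node
        node.chosen_k = k_star
        node.best_run = best_run_at(runs_by_k, k_star)
        Q = node.best_run.Q
        reason = should_terminate(node, cfg, Q=Q)
        if reason:
            _finish(node, reason)
            return node
        children, unassigned = partition_by_assignment(
            indices, Q, cfg.min_cluster_size, sub.pop_labels, cfg.assign_mode
        )
        node.unassigned = unassigned
        reason = should_terminate(node, cfg, Q=Q, children=children)
        if reason:
            _finish(node, reason)
            return node
        for child_idx in children:
            node.children.append(analyze(child_idx, depth + 1))
        return node

    def _finish(node: HierarchyNode, reason: str) -> None:
        node.terminal = True
        node.reason = reason
        counter["component"] += 1
        node.component = counter["component"]

    root = analyze(np.arange(g.n_individuals), depth=1)
    return root


def count_terminal_components(tree: HierarchyNode) -> int:
    return len(tree.terminal_nodes())


def population_component_summary(
    tree: HierarchyNode, g: GenotypeMatrix
) -> tuple[dict[str, dict[int, int]], float]:
    """Per-population component profile and the fraction of 'unique' pops.

    A population is unique iff some terminal component contains individuals
    of that population only AND holds a majority of the population's
    individuals.
    """
    comp_of = np.full(g.n_individuals, -1, dtype=int)
    for node in tree.terminal_nodes():
        comp_of[node.indices] = node.component
    profiles: dict[str, dict[int, int]] = {}
    labels = np.asarray(g.pop_labels, dtype=object)
    for pop in g.populations:
        rows = np.flatnonzero(labels == pop)
        counts: dict[int, int] = {}
        for c in comp_of[rows]:
            counts[int(c)] = counts.get(int(c), 0) + 1
        profiles[pop] = counts
    comp_pops: dict[int, set[str]] = {}
    for pop, counts in profiles.items():
        for c in counts:
            if c >= 0:
                comp_pops.setdefault(c, set()).add(pop)
    unique = 0
    for pop in g.populations:
        counts = profiles[pop]
        n_pop = sum(counts.values())
        for c, cnt in counts.items():
            if c >= 0 and comp_pops[c] == {pop} and cnt * 2 > n_pop:
                unique += 1
                break
    return profiles, unique / len(g.populations)


def hierarchy_to_json(tree: HierarchyNode, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(tree.to_dict(), fh, indent=2)


def hierarchy_to_tsv(tree: HierarchyNode, g: GenotypeMatrix, path: str) -> None:
    """Flat per-individual table: component label and depth-wise path."""
    comp_of = np.full(g.n_individuals, -1, dtype=int)
    path_of = ["" for _ in range(g.n_individuals)]

    def walk(node: HierarchyNode, prefix: str) -> None:
        if node.terminal:
            for i in node.indices:
                comp_of[i] = node.component
                path_of[i] = prefix or "root"
            return
        for ci, child in enumerate(node.children):
            walk(child, f"{prefix}/{ci + 1}" if prefix else str(ci + 1))

    walk(tree, "")
    with open(path, "w") as fh:
        fh.write("individual\tpopulation\tcomponent\tpath\n")
        for i, (ind, pop) in enumerate(zip(g.individual_ids, g.pop_labels)):
            comp = comp_of[i] if comp_of[i] >= 0 else "NA"
            fh.write(f"{ind}\t{pop}\t{comp}\t{path_of[i] or 'NA'}\n")
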