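"""Meta-experiments on delta-K behaviour.

Two designs:

* subsampling: draw population subsets of increasing size, run the K scan
  on each, and summarize how the selected K* moves with the number of
  sampled populations;
* clade composition: draw 4-population samples, classify each by how many
  deep clades (and subclades) it spans, and tabulate how often K* = 2 per
  category, together with the samples' mean pairwise F_ST.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .genotype_data import GenotypeMatrix, subset
from .hierarchical_pipeline import HierConfig, run_level
from .model_selection import SelectionError, select_optimal_k
from .popgen_stats import DistanceMatrix, UPGMANode, pairwise_fst


@dataclass
class SubsampleDesign:
    levels: tuple[int, ...] = (4, 6, 8, 10, 12, 16, 20, 30)
    replicates: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class CladeExperimentDesign:
    n_samples: int = 60
    sample_size: int = 4
    seed: int | None = None


@dataclass
class SubsampleResult:
    records: list[dict]                     # level, replicate, pops, k_star
    summary: dict[int, dict[str, float]]    # per level: min/max/mean/median/prop_k2

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("level\treplicate\tk_star\tpopulations\n")
            for r in self.records:
                fh.write(
                    f"{r['level']}\t{r['replicate']}\t{r['k_star']}\t{','.join(r['pops'])}\n"
                )

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"records": self.records, "summary": self.summary}, fh, indent=2)


def _k_star_for_subset(g_sub: GenotypeMatrix, cfg: HierConfig, seed: int) -> "int | None":
    table, _ = run_level(g_sub, cfg, seed=seed)
    try:
        return select_optimal_k(table)
    except SelectionError:
        return None


def run_subsample_experiment(
    g: GenotypeMatrix, design: SubsampleDesign, cfg: HierConfig
) -> SubsampleResult:
    """K* per (level, replicate) with per-level summaries.

    Populations are drawn without replacement within each replicate.
    """
    pops = g.populations
    for level in design.levels:
        if level > len(pops):
            raise ValueError(f"level {level} exceeds population count {len(pops)}")
    rng = np.random.default_rng(design.seed)
    records: list[dict] = []
    for level in design.levels:
        for rep in range(design.replicates):
            chosen = sorted(rng.choice(len(pops), size=level, replace=False))
            sample = [pops[i] for i in chosen]
            g_sub = subset(g, sample)
            seed = int(rng.integers(0, 2**31 - 1))
            k_star = _k_star_for_subset(g_sub, cfg, seed)
            records.append(
                {"level": level, "replicate": rep + 1, "pops": sample, "k_star": k_star}
            )
    summary: dict[int, dict[str, float]] = {}
    for level in design.levels:
        ks = [r["k_star"] for r in records if r["level"] == level and r["k_star"]]
        if ks:
            arr = np.array(ks, dtype=float)
            summary[level] = {
                "n": len(ks),
                "min": float(arr.min()),
                "max": float(arr.max()),
                "mean": float(arr.mean()),
                "median": float(np.median(arr)),
                "prop_k2": float((arr == 2).mean()),
            }
        else:
            summary[level] = {"n": 0}
    return SubsampleResult(records=records, summary=summary)


# ---------------------------------------------------------------------------
# clade-composition experiment
# ---------------------------------------------------------------------------

CATEGORY_3_4 = "3_or_4_clades"
CATEGORY_2_3SUB = "2_clades_3_subclades"
CATEGORY_2 = "2_clades"
CATEGORY_1 = "1_clade"
CATEGORIES = (CATEGORY_3_4, CATEGORY_2_3SUB, CATEGORY_2, CATEGORY_1)


def classify_sample_by_clades(
    sample_pops: list[str], annotation: dict[str, tuple[str, str]]
) -> str:
    """Category by distinct clade count, refined by subclades at 2 clades."""
    missing = [p for p in sample_pops if p not in annotation]
    if missing:
        raise KeyError(f"populations without clade annotation: {missing}")
    clades = {annotation[p][0] for p in sample_pops}
    subclades = {annotation[p][1] for p in sample_pops}
    if len(clades) >= 3:
        return CATEGORY_3_4
    if len(clades) == 2:
        return CATEGORY_2_3SUB if len(subclades) >= 3 else CATEGORY_2
    return CATEGORY_1


def draw_samples_in_category(
    pops: list[str],
    annotation: dict[str, tuple[str, str]],
    category: str,
    n_samples: int,
    rng: np.random.Generator,
    sample_size: int = 4,
    max_tries: int = 100_000,
) -> list[list[str]]:
    """Rejection-sample population subsets falling in one clade category."""
    out: list[list[str]] = []
    tries = 0
    while len(out) < n_samples:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not draw {n_samples} samples in category {category!r}"
            )
        chosen = sorted(rng.choice(len(pops), size=sample_size, replace=False))
        sample = [pops[i] for i in chosen]
        if classify_sample_by_clades(sample, annotation) == category:
            out.append(sample)
    return out


@dataclass
class CladeExperimentResult:
    records: list[dict]
    summary: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("sample\tcategory\tk_star\tmean_fst\tpopulations\n")
            for r in self.records:
                fh.write(
                    f"{r['sample']}\t{r['category']}\t{r['k_star']}\t"
                    f"{r['mean_fst']:.4f}\t{','.join(r['pops'])}\n"
                )

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"records": self.records, "summary": self.summary}, fh, indent=2)


def _mean_pairwise_fst(g_sub: GenotypeMatrix) -> tuple[float, float]:
    pops = g_sub.populations
    vals = []
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            vals.append(pairwise_fst(g_sub, pops[i], pops[j]))
    arr = np.array(vals)
    return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0


def summarize_clade_records(records: list[dict]) -> dict[str, dict[str, float]]:
    summary: dict[str, dict[str, float]] = {}
    for cat in CATEGORIES:
        rs = [r for r in records if r["category"] == cat]
        ks = [r["k_star"] for r in rs if r["k_star"]]
        fsts = [r["mean_fst"] for r in rs]
        summary[cat] = {
            "n_samples": len(rs),
            "n_k2": sum(1 for k in ks if k == 2),
            "mean_k": float(np.mean(ks)) if ks else float("nan"),
            "mean_fst": float(np.mean(fsts)) if fsts else float("nan"),
            "sd_fst": float(np.std(fsts, ddof=1)) if len(fsts) > 1 else float("nan"),
        }
    return summary


def run_clade_experiment(
    g: GenotypeMatrix,
    design: CladeExperimentDesign,
    cfg: HierConfig,
    annotation: dict[str, tuple[str, str]],
    samples: "list[list[str]] | None" = None,
) -> CladeExperimentResult:
    """Random (or caller-provided) 4-population samples, categorized by clades.

    Per category the summary gives the sample count, the count with K* = 2,
    the mean K* and the mean/s.d. of each sample's mean pairwise F_ST.
    """
    pops = g.populations
    rng = np.random.default_rng(design.seed)
    if samples is None:
        samples = []
        for _ in range(design.n_samples):
            chosen = sorted(rng.choice(len(pops), size=design.sample_size, replace=False))
            samples.append([pops[i] for i in chosen])
    records: list[dict] = []
    for s_no, sample in enumerate(samples, start=1):
        category = classify_sample_by_clades(sample, annotation)
        g_sub = subset(g, sample)
        seed = int(rng.integers(0, 2**31 - 1))
        k_star = _k_star_for_subset(g_sub, cfg, seed)
        mean_fst, _ = _mean_pairwise_fst(g_sub)
        records.append(
            {
                "sample": s_no,
                "category": category,
                "pops": sample,
                "k_star": k_star,
                "mean_fst": mean_fst,
            }
        )
    return CladeExperimentResult(records=records, summary=summarize_clade_records(records))


# ---------------------------------------------------------------------------
# clade annotation from a UPGMA tree
# ---------------------------------------------------------------------------


def _cut_tree(root: UPGMANode, n_parts: int) -> tuple[list[list[str]], bool]:
    """Cut below the (n_parts − 1) highest merges; returns (parts, exact)."""
    heights = sorted(
        (n.height for n in _walk(root) if not n.is_leaf), reverse=True
    )
    n_leaves = len(root.leaf_labels())
    n_parts = min(n_parts, n_leaves)
    if n_parts <= 1:
        return [root.leaf_labels()], True
    threshold = heights[n_parts - 2] if n_parts - 2 < len(heights) else 0.0
    parts: list[list[str]] = []

    def collect(node: UPGMANode) -> None:
        if node.is_leaf or node.height < threshold:
            parts.append(node.leaf_labels())
        else:
            for c in node.children:
                collect(c)

    collect(root)
    return parts, len(parts) == n_parts


def _walk(node: UPGMANode):
    stack = [node]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


def cut_upgma_clades(
    tree: "UPGMANode | DistanceMatrix",
    n_clades: int,
    n_subclades: int = 2,
) -> dict[str, tuple[str, str]]:
    """Annotate each leaf with (clade, subclade) by cutting the UPGMA tree.

    The primary cut yields ``n_clades`` subtrees; inside every clade with at
    least 2 leaves a second, lower cut yields up to ``n_subclades``
    subclades.  When merge-height ties make the requested count unattainable
    the nearest attainable partition is used.
    """
    if isinstance(tree, DistanceMatrix):
        from .popgen_stats import upgma

        tree = upgma(tree)
    leaves = tree.leaf_labels()
    if not (2 <= n_clades <= len(leaves)):
        raise ValueError("n_clades must lie in [2, n_leaves]")
    clades, _ = _cut_tree(tree, n_clades)
    annotation: dict[str, tuple[str, str]] = {}
    # map each clade back to its subtree to cut again for subclades
    for c_no, clade_leaves in enumerate(clades, start=1):
        clade_name = f"clade{c_no}"
        node = _find_subtree(tree, set(clade_leaves))
        if node is None or node.is_leaf or len(clade_leaves) < 2:
            for leaf in clade_leaves:
                annotation[leaf] = (clade_name, f"{clade_name}.1")
            continue
        subs, _ = _cut_tree(node, min(n_subclades, len(clade_leaves)))
        for s_no, sub_leaves in enumerate(subs, start=1):
            for leaf in sub_leaves:
                annotation[leaf] = (clade_name, f"{clade_name}.{s_no}")
    return annotation


def _find_subtree(root: UPGMANode, leaf_set: set[str]) -> "UPGMANode | None":
    for node in _walk(root):
        if set(node.leaf_labels()) == leaf_set:
            return node
    return None
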