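"""Synthetic diploid genotype datasets with known hierarchical differentiation.

Demes sit at the leaves of a rooted :class:`DemeTree`; every edge carries a
drift intensity ``F`` in (0, 1).  Allele frequencies start from a symmetric
Dirichlet draw at the root and are perturbed down each edge with the
standard Dirichlet drift transition

    child ~ Dirichlet(parent * (1 - F) / F)

which keeps ``E[child] = parent`` and gives ``Var[child_j] = F p_j (1 - p_j)``.
Individuals are diploid: two gene copies drawn independently from their
deme's realized frequencies at each locus.

Ground truth for estimator tests is :func:`parametric_gst` computed from the
realized leaf frequencies, not a closed-form pairwise prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_data import MISSING, GenotypeMatrix


@dataclass
class DemeNode:
    """One node of a deme tree. ``f_drift`` is the drift on the edge above."""

    name: str
    f_drift: float | None = None  # None only at the root
    children: list["DemeNode"] = field(default_factory=list)
    n_individuals: int | None = None  # leaves only
    clade: str | None = None
    subclade: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class DemeTree:
    """Rooted tree of demes with per-edge drift and per-leaf sample sizes."""

    root: DemeNode

    def __post_init__(self) -> None:
        leaves = self.leaves()
        if len(leaves) < 2:
            raise ValueError("a deme tree needs at least 2 leaves")
        names = [lf.name for lf in leaves]
        if len(set(names)) != len(names):
            raise ValueError("leaf labels must be unique")
        for node in self.walk():
            if node is not self.root:
                if node.f_drift is None or not (0.0 < node.f_drift < 1.0):
                    raise ValueError(
                        f"edge above {node.name!r} must carry F strictly inside (0,1)"
                    )
            if node.is_leaf and (node.n_individuals is None or node.n_individuals < 1):
                raise ValueError(f"leaf {node.name!r} needs a sample size >= 1")

    def walk(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[DemeNode]:
        return [n for n in self.walk() if n.is_leaf]

    def clade_annotation(self) -> dict[str, tuple[str, str]]:
        """Map each leaf label to its (clade, subclade) tags.

        Untagged leaves inherit their clade name as subclade.
        """
        out = {}
        for leaf in self.leaves():
            clade = leaf.clade if leaf.clade is not None else leaf.name
            sub = leaf.subclade if leaf.subclade is not None else clade
            out[leaf.name] = (clade, sub)
        return out

    def to_newick(self) -> str:
        def fmt(node: DemeNode) -> str:
            if node.is_leaf:
                s = node.name
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")" + (node.name or "")
            if node.f_drift is not None:
                s += f":{node.f_drift:g}"
            return s

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str, sizes: dict[str, int]) -> "DemeTree":
        """Parse a Newick string whose branch lengths are drift F values.

        ``sizes`` maps each leaf label to its diploid sample size.
        """
        text = newick.strip()
        if not text.endswith(";"):
            raise ValueError("newick string must end with ';'")
        pos = 0

        def parse_node() -> DemeNode:
            nonlocal pos
            node = DemeNode(name="")
            if text[pos] == "(":
                pos += 1
                while True:
                    node.children.append(parse_node())
                    if text[pos] == ",":
                        pos += 1
                        continue
                    if text[pos] == ")":
                        pos += 1
                        break
                    raise ValueError(f"malformed newick near offset {pos}")
            start = pos
            while pos < len(text) and text[pos] not in ",():;":
                pos += 1
            node.name = text[start:pos]
            if pos < len(text) and text[pos] == ":":
                pos += 1
                start = pos
                while pos < len(text) and text[pos] not in ",();":
                    pos += 1
                node.f_drift = float(text[start:pos])
            if node.is_leaf:
                if node.name not in sizes:
                    raise ValueError(f"no sample size for leaf {node.name!r}")
                node.n_individuals = int(sizes[node.name])
            return node

        root = parse_node()
        if text[pos] != ";":
            raise ValueError("trailing characters after newick tree")
        if not root.name:
            root.name = "root"
        return cls(root)


def star_tree(n_demes: int, f_drift: float, sizes: "int | list[int]" = 20) -> DemeTree:
    """A star tree: every deme drifts independently from the root with equal F."""
    if isinstance(sizes, int):
        sizes = [sizes] * n_demes
    root = DemeNode(name="root")
    root.children = [
        DemeNode(name=f"D{i + 1}", f_drift=f_drift, n_individuals=sizes[i])
        for i in range(n_demes)
    ]
    return DemeTree(root)


def clade_tree(
    clade_sizes: list[int],
    f_deep: float,
    f_leaf: float,
    leaf_size: int = 15,
) -> DemeTree:
    """Two-level tree: clades hang off the root, demes hang off each clade."""
    root = DemeNode(name="root")
    d = 0
    for c, n in enumerate(clade_sizes):
        clade = DemeNode(name=f"C{c + 1}", f_drift=f_deep, clade=f"C{c + 1}")
        for _ in range(n):
            d += 1
            clade.children.append(
                DemeNode(
                    name=f"D{d}",
                    f_drift=f_leaf,
                    n_individuals=leaf_size,
                    clade=f"C{c + 1}",
                    subclade=f"C{c + 1}",
                )
            )
        root.children.append(clade)
    return DemeTree(root)


@dataclass
class SimulationSpec:
    """Parameters of one synthetic dataset."""

    tree: DemeTree
    n_loci: int = 12
    alleles_per_locus: "int | list[int]" = 8
    ancestral_lambda: float = 1.0
    missing_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        js = self.locus_allele_counts()
        if any(j < 2 for j in js):
            raise ValueError("every locus needs >= 2 alleles")
        if self.ancestral_lambda <= 0:
            raise ValueError("ancestral_lambda must be > 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")

    def locus_allele_counts(self) -> list[int]:
        if isinstance(self.alleles_per_locus, int):
            return [self.alleles_per_locus] * self.n_loci
        if len(self.alleles_per_locus) != self.n_loci:
            raise ValueError("alleles_per_locus list length must equal n_loci")
        return list(self.alleles_per_locus)


def spec_to_dict(spec: SimulationSpec) -> dict:
    """Serializable form: tree as Newick (F as branch lengths) + leaf sizes."""
    return {
        "tree_newick": spec.tree.to_newick(),
        "leaf_sizes": {lf.name: lf.n_individuals for lf in spec.tree.leaves()},
        "n_loci": spec.n_loci,
        "alleles_per_locus": spec.alleles_per_locus,
        "ancestral_lambda": spec.ancestral_lambda,
        "missing_rate": spec.missing_rate,
        "seed": spec.seed,
    }


def spec_from_dict(payload: dict) -> SimulationSpec:
    tree = DemeTree.from_newick(payload["tree_newick"], payload["leaf_sizes"])
    return SimulationSpec(
        tree=tree,
        n_loci=payload.get("n_loci", 12),
        alleles_per_locus=payload.get("alleles_per_locus", 8),
        ancestral_lambda=payload.get("ancestral_lambda", 1.0),
        missing_rate=payload.get("missing_rate", 0.0),
        seed=payload.get("seed"),
    )


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_ancestral_frequencies(
    spec: SimulationSpec, rng: "np.random.Generator | int | None" = None
) -> list[np.ndarray]:
    """Draw per-locus ancestral frequency vectors from symmetric Dirichlet(λ_A)."""
    rng = _rng(rng if rng is not None else spec.seed)
    return [
        rng.dirichlet(np.full(j, spec.ancestral_lambda))
        for j in spec.locus_allele_counts()
    ]


def drift_frequencies(
    parent_freqs: np.ndarray, f_drift: float, rng: "np.random.Generator | int | None" = None
) -> np.ndarray:
    """One Dirichlet drift step: child ~ Dirichlet(parent (1-F)/F)."""
    if not (0.0 < f_drift < 1.0):
        raise ValueError("F must lie strictly inside (0, 1)")
    parent = np.asarray(parent_freqs, dtype=float)
    if abs(parent.sum() - 1.0) > 1e-8:
        raise ValueError("parent frequencies must sum to 1")
    rng = _rng(rng)
    conc = parent * (1.0 - f_drift) / f_drift
    # guard: Dirichlet with a zero concentration component is degenerate there
    conc = np.maximum(conc, 1e-12)
    child = rng.dirichlet(conc)
    return child


def simulate_genotypes(
    spec: SimulationSpec, seed: "int | None" = None
) -> tuple[GenotypeMatrix, dict[str, list[np.ndarray]]]:
    """Simulate a genotype matrix and return realized per-deme frequencies.

    Frequencies drift from the root down every edge; each individual then
    receives two independent gene copies per locus from its deme's realized
    frequencies.  Missing calls are injected uniformly at ``missing_rate``.
    """
    rng = _rng(seed if seed is not None else spec.seed)
    ancestral = sample_ancestral_frequencies(spec, rng)

    deme_freqs: dict[str, list[np.ndarray]] = {}

    def descend(node: DemeNode, freqs: list[np.ndarray]) -> None:
        if node.is_leaf:
            deme_freqs[node.name] = freqs
            return
        for child in node.children:
            child_freqs = [drift_frequencies(f, child.f_drift, rng) for f in freqs]
            descend(child, child_freqs)

    descend(spec.tree.root, ancestral)

    leaves = spec.tree.leaves()
    ids: list[str] = []
    pops: list[str] = []
    blocks: list[np.ndarray] = []
    for leaf in leaves:
        n = leaf.n_individuals
        freqs = deme_freqs[leaf.name]
        block = np.empty((n, spec.n_loci, 2), dtype=np.int64)
        for l, p in enumerate(freqs):
            block[:, l, :] = rng.choice(len(p), size=(n, 2), p=p)
        blocks.append(block)
        ids.extend(f"{leaf.name}_{i + 1}" for i in range(n))
        pops.extend([leaf.name] * n)

    alleles = np.concatenate(blocks, axis=0)
    if spec.missing_rate > 0:
        miss = rng.random(alleles.shape) < spec.missing_rate
        alleles[miss] = MISSING
    g = GenotypeMatrix(ids, pops, alleles, [f"L{j + 1}" for j in range(spec.n_loci)])
    return g, deme_freqs


def parametric_gst(
    deme_freqs: dict[str, list[np.ndarray]], demes: "list[str] | None" = None
) -> float:
    """Gst = (Ht - Hs) / Ht from realized deme frequencies, summed over loci.

    Hs is the mean within-deme expected heterozygosity, Ht the expected
    heterozygosity of the pooled (unweighted mean) frequencies; both are
    summed over loci before taking the ratio.
    """
    if demes is None:
        demes = list(deme_freqs)
    if len(demes) < 2:
        raise ValueError("parametric Gst needs >= 2 demes")
    n_loci = len(deme_freqs[demes[0]])
    hs_sum = ht_sum = 0.0
    for l in range(n_loci):
        mat = np.stack([deme_freqs[d][l] for d in demes])  # (D, J)
        hs_sum += float(np.mean(1.0 - (mat**2).sum(axis=1)))
        pbar = mat.mean(axis=0)
        ht_sum += float(1.0 - (pbar**2).sum())
    if ht_sum <= 0:
        raise ValueError("all loci monomorphic across demes; Gst undefined")
    return (ht_sum - hs_sum) / ht_sum


# ---------------------------------------------------------------------------
# study-mimic dataset
# ---------------------------------------------------------------------------


def study_mimic_tree(
    rng: "np.random.Generator | int | None" = None,
    f_top: float = 0.12,
    f_clade: float = 0.3,
    f_clade_iv: float = 0.45,
    f_sub: float = 0.12,
    f_leaf: float = 0.4,
    f_leaf_plain: float = 0.4,
    size_range: tuple[int, int] = (9, 33),
) -> DemeTree:
    """A 38-deme tree with a dominant binary split over 4 clades.

    Topology: the root splits into one branch holding clades I (4 demes),
    II (9 demes, subclades 6+3) and IV (2 demes, the most divergent), and a
    second branch that is clade III (23 demes, subclades 12+11).  The
    dominant two-way split is what makes delta-K collapse to K = 2 on large
    population samples while the four clades remain clearly separated.

    Per-edge drift defaults put between-clade pairwise differentiation in
    roughly the 0.3-0.7 band (mean ~0.5) and within-clade differentiation
    near 0.25-0.3, so even same-clade demes are clearly distinct.  Leaf
    sample sizes are uniform on ``size_range``.
    """
    rng = _rng(rng)
    layout = {
        "I": ([4], f_clade),
        "II": ([6, 3], f_clade),
        "IV": ([2], f_clade_iv),
        "III": ([12, 11], f_clade),
    }
    root = DemeNode(name="root")
    super1 = DemeNode(name="super1", f_drift=f_top)
    root.children.append(super1)
    d = 0
    for clade_name, (sub_sizes, f_edge) in layout.items():
        if clade_name == "III":
            clade = DemeNode(name="cladeIII", f_drift=f_edge, clade="III")
            root.children.append(clade)
        else:
            clade = DemeNode(name=f"clade{clade_name}", f_drift=f_edge, clade=clade_name)
            super1.children.append(clade)
        for s, n_sub in enumerate(sub_sizes):
            sub_name = f"{clade_name}.{s + 1}"
            if len(sub_sizes) == 1:
                parent, leaf_f = clade, f_leaf_plain
            else:
                sub = DemeNode(name=f"sub{sub_name}", f_drift=f_sub,
                               clade=clade_name, subclade=sub_name)
                clade.children.append(sub)
                parent, leaf_f = sub, f_leaf
            for _ in range(n_sub):
                d += 1
                parent.children.append(
                    DemeNode(
                        name=f"P{d}",
                        f_drift=leaf_f,
                        n_individuals=int(rng.integers(size_range[0], size_range[1] + 1)),
                        clade=clade_name,
                        subclade=sub_name,
                    )
                )
    return DemeTree(root)


def study_mimic_spec(seed: "int | None" = None, n_loci: int = 12, alleles_per_locus: int = 8) -> SimulationSpec:
    """Simulation spec mirroring the study's data shape (38 demes, 12 SSR loci)."""
    tree = study_mimic_tree(_rng(seed))
    return SimulationSpec(
        tree=tree,
        n_loci=n_loci,
        alleles_per_locus=alleles_per_locus,
        ancestral_lambda=1.0,
        missing_rate=0.0,
        seed=seed,
    )
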