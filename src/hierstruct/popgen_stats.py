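"""Supporting population-genetic statistics.

Pairwise F_ST (Weir–Cockerham θ, default, or Nei Gst), the island-model
gene-flow conversion Nm = (1 − F_ST)/(4 F_ST), Nei's genetic distance
(standard and sample-size-unbiased variants), a three-level AMOVA with
permutation tests, UPGMA clustering to Newick, and principal coordinates
analysis by Gower double-centering.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .genotype_data import AlleleFrequencyTable, GenotypeMatrix, allele_frequencies


@dataclass
class DistanceMatrix:
    """Symmetric non-negative matrix over population labels, zero diagonal."""

    labels: list[str]
    values: np.ndarray
    name: str = "distance"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match label count")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if np.abs(np.diag(self.values)).max(initial=0.0) != 0.0:
            raise ValueError("diagonal must be exactly 0")
        if np.isnan(self.values).any() or (self.values < 0).any():
            raise ValueError("entries must be finite and non-negative")

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str, name: str = "distance") -> "DistanceMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = [ln.rstrip("\n").split("\t") for ln in fh if ln.strip()]
        values = np.array([[float(v) for v in r[1:]] for r in rows])
        return cls(labels=header, values=values, name=name)


# ---------------------------------------------------------------------------
# F_ST estimators
# ---------------------------------------------------------------------------


def _locus_arrays(g: GenotypeMatrix, pops: list[str], locus: int):
    """Per-pop sample sizes, allele freqs and observed-het freqs at one locus.

    Individuals with any missing call at the locus are excluded (so each
    retained individual contributes a full genotype).
    """
    per_pop = []
    alleles_seen: set[int] = set()
    for pop in pops:
        rows = g.pop_indices(pop)
        geno = g.alleles[rows, locus, :]
        ok = (geno != g.missing_code).all(axis=1)
        geno = geno[ok]
        per_pop.append(geno)
        alleles_seen.update(int(a) for a in geno.ravel())
    order = sorted(alleles_seen)
    if len(order) < 2:
        return None  # monomorphic or empty locus: no information
    J = len(order)
    idx = {a: j for j, a in enumerate(order)}
    n = np.array([len(geno) for geno in per_pop], dtype=float)
    if (n == 0).any():
        return None
    p = np.zeros((len(pops), J))
    h = np.zeros((len(pops), J))
    for i, geno in enumerate(per_pop):
        for a1, a2 in geno:
            p[i, idx[int(a1)]] += 1
            p[i, idx[int(a2)]] += 1
            if a1 != a2:
                h[i, idx[int(a1)]] += 1
                h[i, idx[int(a2)]] += 1
        p[i] /= 2 * n[i]
        h[i] /= n[i]
    return n, p, h


def wc_theta(g: GenotypeMatrix, pops: "list[str] | None" = None) -> float:
    """Weir–Cockerham θ over >= 2 populations, summed over loci and alleles."""
    if pops is None:
        pops = g.populations
    if len(pops) < 2:
        raise ValueError("theta needs >= 2 populations")
    num = den = 0.0
    informative = False
    for l in range(g.n_loci):
        arrs = _locus_arrays(g, pops, l)
        if arrs is None:
            continue
        n, p, h = arrs
        r = len(pops)
        nbar = n.mean()
        if nbar <= 1:
            continue
        nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
        if nc <= 0:
            continue
        informative = True
        pbar = (n[:, None] * p).sum(axis=0) / (r * nbar)
        s2 = (n[:, None] * (p - pbar[None, :]) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n[:, None] * h).sum(axis=0) / (r * nbar)
        pq = pbar * (1.0 - pbar)
        a = (nbar / nc) * (
            s2 - (pq - ((r - 1) / r) * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pq - ((r - 1) / r) * s2 - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
        num += a.sum()
        den += (a + b + c).sum()
    if not informative or den == 0.0:
        raise ValueError("no shared polymorphic loci between the populations")
    return float(num / den)


def gst_pair(g: GenotypeMatrix, pop_a: str, pop_b: str) -> float:
    """Nei Gst between two populations from sample allele frequencies."""
    table = allele_frequencies(g)
    hs_sum = ht_sum = 0.0
    informative = False
    for l in range(g.n_loci):
        fa = table.freqs.get((pop_a, l))
        fb = table.freqs.get((pop_b, l))
        if not fa or not fb:
            continue
        order = sorted(set(fa) | set(fb))
        va = np.array([fa.get(a, 0.0) for a in order])
        vb = np.array([fb.get(a, 0.0) for a in order])
        hs = 0.5 * ((1 - (va**2).sum()) + (1 - (vb**2).sum()))
        pbar = (va + vb) / 2.0
        ht = 1.0 - (pbar**2).sum()
        if ht > 0:
            informative = True
        hs_sum += hs
        ht_sum += ht
    if not informative or ht_sum == 0.0:
        raise ValueError("no shared polymorphic loci between the populations")
    return float(min(max((ht_sum - hs_sum) / ht_sum, 0.0), 1.0))


def pairwise_fst(g: GenotypeMatrix, pop_a: str, pop_b: str, estimator: str = "wc") -> float:
    """Pairwise F_ST between two populations.

    ``estimator="wc"`` gives Weir–Cockerham θ (may be slightly negative,
    reported raw); ``"gst"`` gives Nei Gst in [0, 1].
    """
    if estimator == "wc":
        return wc_theta(g, [pop_a, pop_b])
    if estimator == "gst":
        return gst_pair(g, pop_a, pop_b)
    raise ValueError(f"unknown estimator {estimator!r}")


def pairwise_fst_matrix(
    g: GenotypeMatrix, estimator: str = "wc", clip_negative: bool = True
) -> DistanceMatrix:
    """All pairwise F_ST values as a DistanceMatrix (negatives clipped to 0)."""
    pops = g.populations
    n = len(pops)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = pairwise_fst(g, pops[i], pops[j], estimator)
            if clip_negative:
                v = max(v, 0.0)
            m[i, j] = m[j, i] = v
    return DistanceMatrix(labels=pops, values=m, name=f"fst_{estimator}")


def nm_from_fst(fst: float) -> float:
    """Island-model gene flow Nm = (1 − F_ST) / (4 F_ST) for F_ST in (0, 1]."""
    if not (0.0 < fst <= 1.0):
        raise ValueError("F_ST must lie in (0, 1]; Nm is undefined otherwise")
    return (1.0 - fst) / (4.0 * fst)


def fst_distribution_summary(values: "np.ndarray | DistanceMatrix") -> dict[str, float]:
    """min/max/mean/s.d. summary of a set of pairwise F_ST values."""
    if isinstance(values, DistanceMatrix):
        values = values.upper_triangle()
    arr = np.asarray(values, dtype=float)
    if arr.size < 1:
        raise ValueError("need at least one pairwise value")
    return {
        "min": float(arr.min()),
        "max": float(arr.max()),
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
    }


# ---------------------------------------------------------------------------
# Nei's genetic distance
# ---------------------------------------------------------------------------


def _pop_locus_vectors(table: AlleleFrequencyTable, pop_a: str, pop_b: str):
    for l in range(len(table.locus_names)):
        fa = table.freqs.get((pop_a, l))
        fb = table.freqs.get((pop_b, l))
        if not fa or not fb:
            continue
        order = sorted(set(fa) | set(fb))
        yield (
            np.array([fa.get(x, 0.0) for x in order]),
            np.array([fb.get(x, 0.0) for x in order]),
            table.sample_size[(pop_a, l)],
            table.sample_size[(pop_b, l)],
        )


def nei_distance(
    g_or_table: "GenotypeMatrix | AlleleFrequencyTable",
    pop_a: str,
    pop_b: str,
    variant: str = "standard",
) -> float:
    """Nei's genetic distance D = −ln I between two populations.

    ``standard``: I = J_ab / sqrt(J_a J_b) with J terms averaged over loci.
    ``unbiased``: J_a and J_b corrected for sample size, (2n Σp² − 1)/(2n − 1);
    the unbiased D can dip below 0 and is reported raw.  Returns +inf when
    the populations share no alleles at any locus.
    """
    if variant not in ("standard", "unbiased"):
        raise ValueError(f"unknown variant {variant!r}")
    table = (
        g_or_table
        if isinstance(g_or_table, AlleleFrequencyTable)
        else allele_frequencies(g_or_table)
    )
    jaa = jbb = jab = 0.0
    n_loci = 0
    for va, vb, na, nb in _pop_locus_vectors(table, pop_a, pop_b):
        ja = float((va**2).sum())
        jb = float((vb**2).sum())
        if variant == "unbiased":
            if na < 2 or nb < 2:
                raise ValueError("unbiased variant needs >= 2 gene copies per pop")
            ja = (na * ja - 1.0) / (na - 1.0)
            jb = (nb * jb - 1.0) / (nb - 1.0)
        jaa += ja
        jbb += jb
        jab += float((va * vb).sum())
        n_loci += 1
    if n_loci == 0:
        raise ValueError("no shared locus data between the populations")
    if jab <= 0.0:
        return math.inf
    identity = (jab / n_loci) / math.sqrt((jaa / n_loci) * (jbb / n_loci))
    return -math.log(identity)


def nei_distance_matrix(g: GenotypeMatrix, variant: str = "standard") -> DistanceMatrix:
    table = allele_frequencies(g)
    pops = g.populations
    n = len(pops)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = nei_distance(table, pops[i], pops[j], variant)
            m[i, j] = m[j, i] = max(v, 0.0)
    return DistanceMatrix(labels=pops, values=m, name=f"nei_{variant}")


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


@dataclass
class AMOVAResult:
    components: dict[str, float]          # raw variance components
    percentages: dict[str, float]         # floored at 0 before normalizing
    phi: dict[str, float]                 # phi_CT, phi_SC, phi_ST
    p_values: dict[str, float]
    df: dict[str, int]
    ss: dict[str, float]
    negative_flagged: bool = False
    n_permutations: int = 0


def genotype_mismatch_matrix(g: GenotypeMatrix) -> np.ndarray:
    """Pairwise inter-individual distance: differing allele copies per locus.

    For two single-locus diploid genotypes the distance is the minimum number
    of differing copies under optimal pairing (0, 1 or 2), summed over loci.
    Loci where either individual has a missing call contribute 0 for that
    pair.
    """
    n = g.n_individuals
    d = np.zeros((n, n))
    for l in range(g.n_loci):
        geno = np.sort(g.alleles[:, l, :], axis=1)
        ok = (g.alleles[:, l, :] != g.missing_code).all(axis=1)
        a, b = geno[:, 0], geno[:, 1]
        same1 = (a[:, None] == a[None, :]).astype(np.int8) + (
            b[:, None] == b[None, :]
        ).astype(np.int8)
        same2 = (a[:, None] == b[None, :]).astype(np.int8) + (
            b[:, None] == a[None, :]
        ).astype(np.int8)
        shared = np.maximum(same1, same2)
        mism = (2 - shared).astype(float)
        valid = ok[:, None] & ok[None, :]
        d += np.where(valid, mism, 0.0)
    np.fill_diagonal(d, 0.0)
    return d


def _amova_components(d2: np.ndarray, pop_of: np.ndarray, grp_of: np.ndarray):
    """Variance components from a squared-distance matrix and assignments."""
    n = d2.shape[0]
    pops = np.unique(pop_of)
    grps = np.unique(grp_of)
    P, G = len(pops), len(grps)

    def ss_within(mask: np.ndarray) -> float:
        idx = np.flatnonzero(mask)
        if idx.size < 2:
            return 0.0
        sub = d2[np.ix_(idx, idx)]
        return float(sub.sum() / (2.0 * idx.size))

    ss_total = float(d2.sum() / (2.0 * n))
    ss_wp = sum(ss_within(pop_of == p) for p in pops)
    ss_wg = sum(ss_within(grp_of == gr) for gr in grps)
    ss_ag = ss_total - ss_wg
    ss_ap = ss_wg - ss_wp

    df_ag, df_ap, df_wp = G - 1, P - G, n - P
    if df_wp <= 0 or df_ap < 0:
        raise ValueError("degenerate design for AMOVA")
    ms_wp = ss_wp / df_wp
    sizes = {p: int((pop_of == p).sum()) for p in pops}
    gsize = {gr: int((grp_of == gr).sum()) for gr in grps}
    pop_grp = {p: grp_of[pop_of == p][0] for p in pops}
    sum_n2_over_g = sum(sizes[p] ** 2 / gsize[pop_grp[p]] for p in pops)
    sum_n2_over_n = sum(sizes[p] ** 2 for p in pops) / n
    sum_g2_over_n = sum(gsize[gr] ** 2 for gr in grps) / n

    sigma_c = ms_wp
    if df_ap > 0:
        n_prime = (n - sum_n2_over_g) / df_ap
        ms_ap = ss_ap / df_ap
        sigma_b = (ms_ap - sigma_c) / n_prime if n_prime > 0 else 0.0
    else:
        sigma_b = 0.0
    if df_ag > 0:
        n_dprime = (sum_n2_over_g - sum_n2_over_n) / df_ag
        n_tprime = (n - sum_g2_over_n) / df_ag
        ms_ag = ss_ag / df_ag
        sigma_a = (ms_ag - sigma_c - n_dprime * sigma_b) / n_tprime if n_tprime > 0 else 0.0
    else:
        sigma_a = 0.0
    return (
        (sigma_a, sigma_b, sigma_c),
        {"among_groups": df_ag, "among_pops_within_groups": df_ap, "within_pops": df_wp},
        {"among_groups": ss_ag, "among_pops_within_groups": ss_ap, "within_pops": ss_wp,
         "total": ss_total},
    )


def _phis(sigma_a: float, sigma_b: float, sigma_c: float) -> dict[str, float]:
    tot = sigma_a + sigma_b + sigma_c
    return {
        "phi_CT": sigma_a / tot if tot > 0 else 0.0,
        "phi_SC": sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) > 0 else 0.0,
        "phi_ST": (sigma_a + sigma_b) / tot if tot > 0 else 0.0,
    }


def amova_three_level(
    g: GenotypeMatrix,
    grouping: dict[str, str],
    n_permutations: int = 999,
    seed: "int | None" = None,
) -> AMOVAResult:
    """Three-level AMOVA (among groups / among pops within groups / within pops).

    ``grouping`` maps every population label to a group label.  Permutation
    p-values: phi_ST permutes individuals freely, phi_SC permutes individuals
    among populations within their group, phi_CT permutes whole populations
    among groups.
    """
    pops = g.populations
    missing = [p for p in pops if p not in grouping]
    if missing:
        raise ValueError(f"grouping does not cover populations: {missing}")
    groups = sorted(set(grouping[p] for p in pops))
    if len(groups) < 2:
        raise ValueError("need >= 2 groups; use a two-level AMOVA otherwise")

    d2 = genotype_mismatch_matrix(g)
    pop_ids = {p: i for i, p in enumerate(pops)}
    grp_ids = {gr: i for i, gr in enumerate(groups)}
    pop_of = np.array([pop_ids[p] for p in g.pop_labels])
    grp_of = np.array([grp_ids[grouping[p]] for p in g.pop_labels])

    (sa, sb, sc), df, ss = _amova_components(d2, pop_of, grp_of)
    phi = _phis(sa, sb, sc)

    flagged = sa < 0 or sb < 0 or sc < 0
    fl = [max(sa, 0.0), max(sb, 0.0), max(sc, 0.0)]
    tot = sum(fl)
    pct = [100.0 * v / tot for v in fl] if tot > 0 else [0.0, 0.0, 100.0]

    rng = np.random.default_rng(seed)
    counts = {"phi_ST": 0, "phi_SC": 0, "phi_CT": 0}
    pop_grp_arr = np.array([grp_ids[grouping[p]] for p in pops])
    for _ in range(n_permutations):
        # phi_ST: shuffle individuals across the whole design
        perm = rng.permutation(g.n_individuals)
        (pa, pb, pc), _, _ = _amova_components(d2, pop_of[perm], grp_of[perm])
        if _phis(pa, pb, pc)["phi_ST"] >= phi["phi_ST"] - 1e-12:
            counts["phi_ST"] += 1
        # phi_SC: shuffle individuals among pops within their group
        perm2 = np.arange(g.n_individuals)
        for gr in range(len(groups)):
            idx = np.flatnonzero(grp_of == gr)
            perm2[idx] = idx[rng.permutation(idx.size)]
        (pa, pb, pc), _, _ = _amova_components(d2, pop_of[perm2], grp_of)
        if _phis(pa, pb, pc)["phi_SC"] >= phi["phi_SC"] - 1e-12:
            counts["phi_SC"] += 1
        # phi_CT: shuffle whole populations among groups
        pg = pop_grp_arr[rng.permutation(len(pops))]
        grp_perm = pg[pop_of]
        (pa, pb, pc), _, _ = _amova_components(d2, pop_of, grp_perm)
        if _phis(pa, pb, pc)["phi_CT"] >= phi["phi_CT"] - 1e-12:
            counts["phi_CT"] += 1

    p_values = {
        k: (counts[k] + 1.0) / (n_permutations + 1.0) if n_permutations else float("nan")
        for k in counts
    }
    return AMOVAResult(
        components={"among_groups": sa, "among_pops_within_groups": sb, "within_pops": sc},
        percentages={
            "among_groups": pct[0],
            "among_pops_within_groups": pct[1],
            "within_pops": pct[2],
        },
        phi=phi,
        p_values=p_values,
        df=df,
        ss=ss,
        negative_flagged=flagged,
        n_permutations=n_permutations,
    )


def amova_to_json(result: AMOVAResult, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "components": result.components,
                "percentages": result.percentages,
                "phi": result.phi,
                "p_values": result.p_values,
                "df": result.df,
                "ss": result.ss,
                "negative_flagged": result.negative_flagged,
                "n_permutations": result.n_permutations,
            },
            fh,
            indent=2,
        )


def amova_table(result: AMOVAResult) -> str:
    """Human-readable AMOVA summary table."""
    rows = [
        ("Among groups", "among_groups", "phi_CT"),
        ("Among populations within groups", "among_pops_within_groups", "phi_SC"),
        ("Within populations", "within_pops", "phi_ST"),
    ]
    lines = [
        f"{'Source':<34}{'df':>5}{'SS':>12}{'Var comp':>12}{'%':>8}{'Phi':>9}{'P':>9}"
    ]
    for label, key, phi_key in rows:
        p = result.p_values.get(phi_key, float("nan"))
        lines.append(
            f"{label:<34}{result.df[key]:>5}{result.ss[key]:>12.3f}"
            f"{result.components[key]:>12.4f}{result.percentages[key]:>8.2f}"
            f"{result.phi[phi_key]:>9.4f}{p:>9.4f}"
        )
    lines.append(f"{'Total':<34}{sum(result.df.values()):>5}{result.ss['total']:>12.3f}")
    if result.negative_flagged:
        lines.append("note: negative variance component floored at 0 for percentages")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------


@dataclass
class UPGMANode:
    height: float
    label: "str | None" = None
    children: list["UPGMANode"] = field(default_factory=list)
    order: int = 0  # smallest original leaf index below; fixes emission order

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaf_labels())
        return out

    def newick(self) -> str:
        def fmt(node: UPGMANode, parent_height: float) -> str:
            bl = parent_height - node.height
            if node.is_leaf:
                return f"{node.label}:{bl:g}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}):{bl:g}"

        if self.is_leaf:
            return f"{self.label};"
        inner = ",".join(fmt(c, self.height) for c in self.children)
        return f"({inner});"


def upgma(d: DistanceMatrix) -> UPGMANode:
    """Size-weighted average-linkage agglomeration; leaf height 0, merge at d/2.

    Ties break toward the lexicographically smallest active-cluster index
    pair, which makes the result deterministic.
    """
    n = len(d.labels)
    if n < 2:
        raise ValueError("UPGMA needs >= 2 taxa")
    if np.isnan(d.values).any() or (d.values < 0).any():
        raise ValueError("distances must be finite and non-negative")
    nodes: dict[int, UPGMANode] = {
        i: UPGMANode(height=0.0, label=lab, order=i) for i, lab in enumerate(d.labels)
    }
    sizes = {i: 1 for i in range(n)}
    dist = {(i, j): float(d.values[i, j]) for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(nodes) > 1:
        (i, j), dij = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        pair = sorted([nodes[i], nodes[j]], key=lambda nd: nd.order)
        new = UPGMANode(height=dij / 2.0, children=pair, order=pair[0].order)
        si, sj = sizes[i], sizes[j]
        del nodes[i], nodes[j]
        remaining = list(nodes)
        for k in remaining:
            a, b = (min(i, k), max(i, k)), (min(j, k), max(j, k))
            dik, djk = dist.pop(a), dist.pop(b)
            dist[(k, next_id)] = (si * dik + sj * djk) / (si + sj)
        del dist[(i, j)]
        nodes[next_id] = new
        sizes[next_id] = si + sj
        next_id += 1
    return nodes.popitem()[1]


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------


@dataclass
class PCoAResult:
    labels: list[str]
    coordinates: np.ndarray       # (n, n_axes) columns ordered by eigenvalue
    eigenvalues: np.ndarray       # all eigenvalues, descending
    proportion_explained: np.ndarray  # over positive eigenvalues only

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            axes = self.coordinates.shape[1]
            fh.write("label\t" + "\t".join(f"axis{i + 1}" for i in range(axes)) + "\n")
            for lab, row in zip(self.labels, self.coordinates):
                fh.write(lab + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("#eigenvalues\t" + "\t".join(f"{v:.6f}" for v in self.eigenvalues) + "\n")


def pcoa(d: DistanceMatrix) -> PCoAResult:
    """Principal coordinates: Gower-center −d²/2, eigendecompose, embed.

    Axes correspond to positive eigenvalues; negative eigenvalues are
    reported but excluded from the variance percentages.
    """
    n = len(d.labels)
    d2 = d.values**2
    jmat = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * jmat @ d2 @ jmat
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10
    coords = evecs[:, pos] * np.sqrt(evals[pos])[None, :]
    pos_sum = evals[pos].sum()
    prop = evals[pos] / pos_sum if pos_sum > 0 else np.zeros(0)
    if not pos.any():
        coords = np.zeros((n, 1))
    return PCoAResult(
        labels=list(d.labels),
        coordinates=coords,
        eigenvalues=evals,
        proportion_explained=prop,
    )
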