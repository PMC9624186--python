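"""Evanno delta-K computation over replicate runs and optimal-K selection.

For each scanned K the table holds the mean L(K) of the replicate runs'
evidence estimates, their sample standard deviation s(K), the first
difference L'(K) = L(K) − L(K−1), the absolute second difference
|L''(K)| = |L(K+1) − 2 L(K) + L(K−1)| and ΔK = |L''(K)| / s(K).

ΔK is undefined at both ends of the scanned range, so it can never point at
K = 1; deciding "no further structure" is the recursion's termination rule,
not this module's job — here we only rank the interior Ks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


class SelectionError(RuntimeError):
    """Raised when no interior K has a usable ΔK (e.g. all s(K) = 0)."""


@dataclass
class KSelectionTable:
    ks: list[int]
    n_runs: dict[int, int]
    mean_lnpd: dict[int, float]
    sd_lnpd: dict[int, float]
    l_prime: dict[int, float] = field(default_factory=dict)
    l_second: dict[int, float] = field(default_factory=dict)
    delta_k: dict[int, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def interior_ks(self) -> list[int]:
        return self.ks[1:-1]

    def to_tsv(self, path: str) -> None:
        """Serialize with harvester-style columns."""
        with open(path, "w") as fh:
            fh.write("K\treps\tmean_LnP_K\tsd_LnP_K\tLn_prime_K\tabs_Ln_second_K\tdelta_K\n")
            for k in self.ks:
                row = [
                    str(k),
                    str(self.n_runs[k]),
                    f"{self.mean_lnpd[k]:.4f}",
                    f"{self.sd_lnpd[k]:.4f}",
                    _fmt(self.l_prime.get(k)),
                    _fmt(self.l_second.get(k)),
                    _fmt(self.delta_k.get(k)),
                ]
                fh.write("\t".join(row) + "\n")


def _fmt(v: "float | None") -> str:
    if v is None:
        return "NA"
    if math.isinf(v):
        return "inf"
    return f"{v:.4f}"


def _lnpd(run) -> float:
    return float(run.lnPD) if hasattr(run, "lnPD") else float(run)


def build_table(runs_by_k: "dict[int, list]") -> KSelectionTable:
    """Build the Evanno table from replicate runs (or raw lnPD floats) per K.

    Requires at least 3 consecutive K values and >= 2 runs at every K.
    """
    ks = sorted(runs_by_k)
    if len(ks) < 3:
        raise ValueError("need at least 3 consecutive K values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError(f"K values must be consecutive, got {ks}")
    table = KSelectionTable(ks=ks, n_runs={}, mean_lnpd={}, sd_lnpd={})
    for k in ks:
        vals = np.array([_lnpd(r) for r in runs_by_k[k]], dtype=float)
        if vals.size < 2:
            raise ValueError(f"K={k} has fewer than 2 runs; s(K) undefined")
        table.n_runs[k] = int(vals.size)
        table.mean_lnpd[k] = float(vals.mean())
        table.sd_lnpd[k] = float(vals.std(ddof=1))
    L = table.mean_lnpd
    for k in ks[1:]:
        table.l_prime[k] = L[k] - L[k - 1]
    for k in ks[1:-1]:
        second = abs(L[k + 1] - 2.0 * L[k] + L[k - 1])
        table.l_second[k] = second
        s = table.sd_lnpd[k]
        if s == 0.0:
            if second == 0.0:
                table.delta_k[k] = 0.0
            else:
                table.delta_k[k] = math.inf
                table.warnings.append(
                    f"K={k}: zero replicate s.d. with nonzero |L''|; delta-K set to +inf"
                )
        else:
            table.delta_k[k] = second / s
    return table


def select_optimal_k(table: KSelectionTable) -> int:
    """K* = argmax ΔK over interior Ks; ties break toward smaller K."""
    interior = table.interior_ks()
    if not interior:
        raise SelectionError("no interior K in the scanned range")
    usable = [k for k in interior if table.sd_lnpd[k] > 0.0 or table.delta_k[k] == math.inf]
    if all(table.sd_lnpd[k] == 0.0 for k in interior):
        raise SelectionError("all replicate standard deviations are zero")
    if not usable:
        raise SelectionError("no interior K with defined delta-K")
    best = usable[0]
    for k in usable[1:]:
        if table.delta_k[k] > table.delta_k[best]:
            best = k
    return best
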