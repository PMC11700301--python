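"""Hypergeometric over-representation analysis against GMT gene sets.

The test asks, for each gene set, whether the hit list contains more set
members than expected by drawing the same number of genes at random from
the quantified universe: p = P[X >= k] with X ~ Hypergeometric(N, K, n).
Reporting follows the convention q <= 0.2 and adjusted p <= 0.05, with
q reported as the BH-adjusted p by default (an optional Storey-style
estimator is available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import FormatError, ValidationError
from .stats import bh_adjust

#: reporting thresholds for over-represented sets
DEFAULT_ORA_CUTOFFS = {"max_q": 0.2, "max_adj_p": 0.05}


@dataclass
class GeneSetCollection:
    """set id -> (description, member ids); members deduplicated, non-empty."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def members(self, set_id: str) -> frozenset[str]:
        return self.sets[set_id][1]

    def add(self, set_id: str, description: str, members: Iterable[str]) -> None:
        members = frozenset(members)
        if not members:
            raise ValidationError(f"gene set {set_id!r} has no members")
        self.sets[set_id] = (description, members)

    def write_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for set_id, (desc, members) in self.sets.items():
                fh.write("\t".join([set_id, desc, *sorted(members)]) + "\n")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (set id, description, members; tab-separated)."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has < 3 fields")
            coll.add(fields[0], fields[1], fields[2:])
    return coll


def collapse_sites_to_genes(site_ids: Iterable[str]) -> list[str]:
    """Collapse PTM-site keys (``ACC-C171`` style) to unique parent accessions."""
    return sorted({s.rsplit("-", 1)[0] for s in site_ids})


def _storey_q(p: np.ndarray) -> np.ndarray:
    """Storey q-values with pi0 estimated at lambda = 0.5."""
    p = np.asarray(p, dtype=float)
    pi0 = min(1.0, np.mean(p > 0.5) / 0.5) if p.size else 1.0
    pi0 = max(pi0, 1.0 / max(p.size, 1))
    return np.minimum(bh_adjust(p) * pi0, 1.0)


def ora(
    hits: Iterable[str],
    universe: Iterable[str],
    sets: GeneSetCollection,
    q_method: str = "bh",
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hits`` within ``universe``.

    Sets are intersected with the universe before testing; sets with no
    members in the universe are dropped.  Returns one row per tested set
    with k, K, n, N, p (upper tail), BH-adjusted p, and q.
    """
    hits = set(hits)
    universe = set(universe)
    stray = hits - universe
    if stray:
        raise ValidationError(f"hit(s) not in universe: {sorted(stray)[:10]}")
    n = len(hits)
    N = len(universe)
    rows = []
    for set_id, (desc, members) in sets.sets.items():
        in_universe = members & universe
        K = len(in_universe)
        if K == 0:
            continue
        k = len(in_universe & hits)
        # P[X >= k] for X ~ Hypergeom(N, K, n)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"set_id": set_id, "description": desc, "k": k, "K": K, "n": n, "N": N, "p": p}
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["adj_p"] = bh_adjust(table["p"].to_numpy())
        if q_method == "bh":
            table["q"] = table["adj_p"]
        elif q_method == "storey":
            table["q"] = _storey_q(table["p"].to_numpy())
        else:
            raise ValidationError(f"unknown q_method {q_method!r}")
    return table


def ora_hits(table: pd.DataFrame, cutoffs=DEFAULT_ORA_CUTOFFS) -> pd.DataFrame:
    """Sets passing the reporting cutoffs (q and adjusted p)."""
    if not len(table):
        return table
    return table[(table["q"] <= cutoffs["max_q"]) & (table["adj_p"] <= cutoffs["max_adj_p"])]
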