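"""Hypergeometric over-representation analysis of metabolite hit lists.

Given a list of significant metabolites (HMDB ids, typically the VIP
selection from PLS-DA) and a pathway library, each pathway is tested for
enrichment with the exact hypergeometric upper tail

    p = sum_{i=k}^{min(K, n)} C(K, i) C(N-K, n-i) / C(N, n)

where k = hits in the list, K = pathway size, n = list size and N = the
universe size.  The universe is an explicit, logged parameter: published
p-values depend on the background library version, so only the mechanism
is reproduced here, not any particular tool's numbers.  Topology-based
"pathway impact" metrics are replaced by an optional degree-based
placeholder that is clearly labelled non-equivalent.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
from scipy import stats


class PathwayError(ValueError):
    pass


@dataclass
class PathwayLibrary:
    """Pathway id -> name + member metabolite ids, plus the test universe."""

    pathways: dict[str, dict]  # id -> {"name": str, "members": set[str]}
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for pid, entry in self.pathways.items():
            entry["members"] = set(entry["members"])
            if not entry["members"]:
                raise PathwayError(f"pathway {pid!r} has no members")
            self.universe |= entry["members"]
        if not self.universe:
            raise PathwayError("empty pathway library")

    @classmethod
    def from_json(cls, path: str | Path) -> "PathwayLibrary":
        payload = json.loads(Path(path).read_text())
        return cls._from_payload(payload)

    @classmethod
    def _from_payload(cls, payload: dict) -> "PathwayLibrary":
        lib = cls(pathways={pid: dict(e) for pid, e in payload["pathways"].items()})
        n_bg = int(payload.get("background_size", 0))
        extra = n_bg - len(lib.universe)
        lib.universe |= {f"BG{i:04d}" for i in range(max(extra, 0))}
        return lib

    @classmethod
    def from_gmt(cls, path: str | Path) -> "PathwayLibrary":
        """Read a GMT file: name <tab> description <tab> member ids."""
        pathways = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise PathwayError(f"malformed GMT line: {line[:60]!r}")
            pathways[fields[0]] = {"name": fields[1] or fields[0], "members": set(fields[2:])}
        return cls(pathways=pathways)


def bundled_library() -> PathwayLibrary:
    """The bundled five-pathway library matching the annotation fixture."""
    with resources.files("chemometab.data").joinpath("pathway_library.json").open() as fh:
        return PathwayLibrary._from_payload(json.load(fh))


def ora_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Exact hypergeometric upper-tail probability of >= k hits.

    Computed through scipy's survival function, which works in log space
    and is numerically stable for large N.
    """
    if not (0 <= k <= min(K, n)):
        raise PathwayError(f"inconsistent counts: k={k}, K={K}, n={n}")
    if K > N or n > N or K < 0 or n < 0:
        raise PathwayError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class ORAResult:
    pathway_id: str
    name: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    hit_ids: tuple[str, ...]
    significant: bool


def enrich(
    metabolite_ids,
    library: PathwayLibrary,
    alpha: float = 0.05,
    adjust: str | None = None,
) -> list[ORAResult]:
    """Test every pathway for over-representation of the given hit list.

    Ids outside the universe are dropped with a warning.  Raw p-values are
    compared against ``alpha``; Benjamini-Hochberg adjustment is available
    via ``adjust="fdr_bh"`` but off by default (the raw-p criterion).
    Results are sorted by p-value.
    """
    ids = list(dict.fromkeys(metabolite_ids))  # unique, order-preserving
    if not ids:
        raise PathwayError("empty metabolite list")
    inside = [m for m in ids if m in library.universe]
    if len(inside) < len(ids):
        dropped = sorted(set(ids) - set(inside))
        warnings.warn(f"dropping {len(dropped)} ids not in universe: {dropped[:5]}...", stacklevel=2)
    if not inside:
        raise PathwayError("no metabolite ids remain after universe filtering")
    n, N = len(inside), len(library.universe)
    results = []
    for pid, entry in library.pathways.items():
        hits = tuple(sorted(entry["members"].intersection(inside)))
        p = ora_pvalue(len(hits), len(entry["members"]), n, N)
        results.append(
            ORAResult(pid, entry["name"], len(hits), len(entry["members"]), n, N, p, hits, p < alpha)
        )
    results.sort(key=lambda r: (r.p_value, r.pathway_id))
    if adjust == "fdr_bh":
        m = len(results)
        adj = 1.0
        # results already sorted ascending by p; step-up from the largest p
        adjusted = [0.0] * m
        for i in range(m - 1, -1, -1):
            adj = min(adj, results[i].p_value * m / (i + 1))
            adjusted[i] = adj
        for r, q in zip(results, adjusted):
            r.p_value = q
            r.significant = q < alpha
    elif adjust is not None:
        raise PathwayError(f"unknown adjustment {adjust!r}")
    return results


def results_frame(results: list[ORAResult]) -> pd.DataFrame:
    """Tabular export (pathway, k/K/n/N, p, flag) plus bubble-plot columns."""
    import numpy as np

    df = pd.DataFrame(
        [
            {
                "pathway_id": r.pathway_id,
                "name": r.name,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_value": r.p_value,
                "significant": r.significant,
                "hits": ";".join(r.hit_ids),
            }
            for r in results
        ]
    )
    df["neg_log10_p"] = -np.log10(df["p_value"])
    # degree-based placeholder for topology impact: hit fraction of the pathway.
    # NOT equivalent to relative-betweenness pathway impact metrics.
    df["impact_placeholder"] = df["k"] / df["K"]
    return df
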