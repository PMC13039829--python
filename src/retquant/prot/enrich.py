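"""Gene-set over-representation of DEP calls (hypergeometric tail).

Gene sets come from a GMT collection (one set per line: name, description,
member ids).  Sets are intersected with the declared universe; the p-value
per set is the upper-tail hypergeometric probability of observing at least
the seen overlap.  A companion export lists per-set member fold changes for
two conditions, the data behind dumbbell-style pathway plots.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .stats import hypergeom_enrichment_p


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT gene-set collection: name<TAB>description<TAB>members..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (needs >= 3 fields): {line[:60]!r}")
        sets[fields[0]] = [m for m in fields[2:] if m]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, name] + list(members)) for name, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def enrich_sets(
    dep_ids: Iterable[str],
    gene_sets: Mapping[str, Sequence[str]],
    universe_ids: Iterable[str],
    top_n: int = 20,
) -> pd.DataFrame:
    """Rank gene sets by hypergeometric over-representation of the DEPs.

    Returns the top-``top_n`` sets ordered by ascending p (stable,
    alphabetical tie-break) with columns overlap ``k``, set size ``m``
    (within the universe), DEP count ``n``, universe size ``N``, ``p`` and
    ``rank``.
    """
    universe = set(universe_ids)
    if not universe:
        raise ValueError("empty universe")
    deps = set(dep_ids) & universe
    if set(dep_ids) - universe:
        raise ValueError("dep_ids must be a subset of the universe")
    N, n = len(universe), len(deps)
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & universe
        m = len(members)
        if m == 0:
            continue
        k = len(members & deps)
        rows.append(
            {
                "set": name,
                "k": k,
                "m": m,
                "n": n,
                "N": N,
                "p": hypergeom_enrichment_p(k, m, n, N),
            }
        )
    table = pd.DataFrame(rows, columns=["set", "k", "m", "n", "N", "p"])
    table = table.sort_values("p", kind="mergesort").head(top_n).reset_index(drop=True)
    table["rank"] = table.index + 1
    return table


def set_member_fold_changes(
    gene_sets: Mapping[str, Sequence[str]],
    dep_table_a: pd.DataFrame,
    dep_table_b: pd.DataFrame,
    set_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-set member fold changes under two conditions (dumbbell export).

    For every member protein present in either DEP table, reports the fold
    change (and significance flag) in each condition; proteins absent from a
    table get NA there.
    """
    names = list(set_names) if set_names is not None else sorted(gene_sets)
    rows = []
    for name in names:
        for pid in sorted(gene_sets[name]):
            in_a, in_b = pid in dep_table_a.index, pid in dep_table_b.index
            if not (in_a or in_b):
                continue
            rows.append(
                {
                    "set": name,
                    "protein_id": pid,
                    "fc_a": dep_table_a.at[pid, "fc"] if in_a else float("nan"),
                    "fc_b": dep_table_b.at[pid, "fc"] if in_b else float("nan"),
                    "is_dep_a": bool(dep_table_a.at[pid, "is_dep"]) if in_a else False,
                    "is_dep_b": bool(dep_table_b.at[pid, "is_dep"]) if in_b else False,
                }
            )
    return pd.DataFrame(
        rows, columns=["set", "protein_id", "fc_a", "fc_b", "is_dep_a", "is_dep_b"]
    )
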