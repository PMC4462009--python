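"""Summary report tables: library mapping statistics, precursor
class-by-context counts, organ distribution and target-function
categories.

Report conventions: percentages are integers rounded half away from
zero; read-count averages are truncated to integers; every marginal
total is recomputed from the underlying per-record table so row and
column sums are internally consistent.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._seq import percent, truncated_mean
from .core import LibraryProfile

CLASS_COLUMNS = ("known", "isomiR", "novel")
CONTEXT_ROWS = ("intergenic", "intron", "exon", "3UTR", "5UTR")


def library_stats_table(profiles: Sequence[LibraryProfile]) -> pd.DataFrame:
    """Per-library mapping statistics (raw, mapped, % mapped)."""
    data = {
        p.name: {
            "raw_reads": p.total_raw,
            "mapped_reads": p.total_mapped,
            "pct_mapped": p.mapped_fraction,
            "unique_tags": p.unique_tags,
        }
        for p in profiles
    }
    return pd.DataFrame(data)


def average_raw_reads(profiles: Iterable[LibraryProfile]) -> int:
    """Truncated mean of raw read counts across libraries."""
    return truncated_mean(p.total_raw for p in profiles)


def class_context_table(precursor_classes: Iterable[str],
                        precursor_contexts: Iterable[str],
                        mature_classes: Mapping[str, str]) -> pd.DataFrame:
    """Class-by-context precursor statistics.

    ``precursor_classes`` / ``precursor_contexts`` are parallel
    per-precursor labels; ``mature_classes`` maps mature sequences to
    their class.  Rows: identified precursors, identified miRNAs and
    one row per genomic context; columns: the three classes plus a
    recomputed total.
    """
    pc = list(precursor_classes)
    ctx = list(precursor_contexts)
    table: dict[str, dict[str, int]] = {}

    def row(name):
        return table.setdefault(name, {c: 0 for c in CLASS_COLUMNS})

    for cls in pc:
        row("identified_precursors")[cls] += 1
    for cls in mature_classes.values():
        row("identified_miRNAs")[cls] += 1
    for cls, context in zip(pc, ctx):
        row(context)[cls] += 1
    ordered = ["identified_precursors", "identified_miRNAs",
               *CONTEXT_ROWS]
    df = pd.DataFrame(
        {c: [table.get(r, {}).get(c, 0) for r in ordered]
         for c in CLASS_COLUMNS},
        index=ordered)
    df["total"] = df.sum(axis=1)
    return df


def bookkeeping_totals(class_counts: Mapping[str, int]) -> dict[str, int]:
    """Recomputed totals from per-class counts: overall total and the
    previously-unpublished sum (everything that is not already known)."""
    total = sum(class_counts.values())
    unpublished = sum(v for k, v in class_counts.items() if k != "known")
    return {"total": total, "previously_unpublished": unpublished}


def organ_distribution_report(
    presence: pd.DataFrame,
    classes: Mapping[str, str],
) -> pd.DataFrame:
    """Per-class organ distribution: counts and integer percentages of
    matures present in all libraries, and organ-specific matures."""
    libs = list(presence.columns)
    rows = {}
    class_list = list(CLASS_COLUMNS) + ["all"]
    for cls in class_list:
        members = [m for m in presence.index
                   if cls == "all" or classes.get(m) == cls]
        if not members:
            rows[cls] = {"n": 0, "all_organs": 0, "pct_all_organs": 0,
                         "organ_specific": 0, "pct_organ_specific": 0}
            continue
        sub = presence.loc[members]
        n_all = int(sub.all(axis=1).sum())
        n_spec = int((sub.sum(axis=1) == 1).sum())
        rows[cls] = {
            "n": len(members),
            "all_organs": n_all,
            "pct_all_organs": percent(n_all, len(members)),
            "organ_specific": n_spec,
            "pct_organ_specific": percent(n_spec, len(members)),
        }
    return pd.DataFrame(rows).T


def target_category_table(target_functions: Mapping[str, str]
                          ) -> pd.DataFrame:
    """Counts of targets per user-supplied functional category."""
    counts: dict[str, int] = {}
    for cat in target_functions.values():
        counts[cat] = counts.get(cat, 0) + 1
    df = pd.DataFrame(sorted(counts.items()),
                      columns=["category", "n_targets"])
    if len(df):
        total = int(df["n_targets"].sum())
        df["pct"] = [percent(n, total) for n in df["n_targets"]]
    return df
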