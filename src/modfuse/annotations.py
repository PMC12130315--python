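"""Multi-source subcellular-localization evidence integration.

Four annotation sources (an in-house imaging screen, UniProt, GO, and
the Human Protein Atlas) each report (entity, location term) records
with their own ordinal evidence scales. Integration proceeds in four
steps: map source vocabularies onto a small consolidated term set
(subterms roll up to their selected parent), keep only the best-graded
record per (entity, term, source), filter to each source's
high-confidence rule, and merge the sources recording per-annotation
support counts.

Records travel as long-format DataFrames with columns
``entity, term, source, grade, confidence, signal`` (the last two are
optional, used by sources whose rule needs them).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "consolidate_terms",
    "rank_evidence",
    "filter_high_confidence",
    "merge_sources",
]

COLUMNS = ["entity", "term", "source", "grade", "confidence", "signal"]


def _frame(annotations) -> pd.DataFrame:
    df = pd.DataFrame(annotations)
    for col in COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[COLUMNS].copy()


def consolidate_terms(annotations, term_map: dict[str, str | None]) -> tuple[pd.DataFrame, int]:
    """Map raw source terms onto the consolidated vocabulary.

    ``term_map`` maps every raw term to its consolidated term (subterm
    expansion is expressed by mapping each subterm to its selected
    parent) or to ``None`` for terms without a counterpart. Unmapped
    terms are dropped; the dropped-record count is returned alongside.
    """
    df = _frame(annotations)
    unknown = set(df["term"]) - set(term_map)
    if unknown:
        raise ValueError(f"term map does not cover: {sorted(unknown)[:10]}")
    mapped = df["term"].map(term_map)
    keep = mapped.notna()
    dropped = int((~keep).sum())
    if dropped:
        logger.info("consolidate_terms: dropped %d records with unmapped terms", dropped)
    out = df[keep].copy()
    out["term"] = mapped[keep]
    return out.reset_index(drop=True), dropped


def rank_evidence(annotations, grade_order: dict[str, list]) -> pd.DataFrame:
    """Collapse duplicates to the single highest-graded record.

    ``grade_order`` lists, per source, grades from highest to lowest
    priority; within equal grades the first-declared record wins.
    Unknown grades raise.
    """
    df = _frame(annotations)
    prio = []
    for _, row in df.iterrows():
        order = grade_order.get(row["source"])
        if order is None:
            raise ValueError(f"no grade order declared for source {row['source']!r}")
        try:
            prio.append(order.index(row["grade"]))
        except ValueError:
            raise ValueError(
                f"unknown grade {row['grade']!r} for source {row['source']!r}") from None
    df = df.assign(_prio=prio, _pos=np.arange(len(df)))
    best = (df.sort_values(["_prio", "_pos"], kind="stable")
              .groupby(["entity", "term", "source"], as_index=False, sort=False)
              .first()
              .sort_values("_pos"))
    return best.drop(columns=["_prio", "_pos"]).reset_index(drop=True)


def filter_high_confidence(annotations, rules: dict[str, dict]) -> pd.DataFrame:
    """Apply per-source high-confidence predicates.

    A rule is a dict with any of: ``grades`` (allowed grade values),
    ``min_confidence`` (threshold on the 1-5 confidence score),
    ``min_signal`` (threshold on the signal proportion). A record from a
    source without a declared rule is an error. Idempotent.
    """
    df = _frame(annotations)
    undeclared = set(df["source"]) - set(rules)
    if undeclared:
        raise ValueError(f"no high-confidence rule for sources: {sorted(undeclared)}")
    keep = np.ones(len(df), dtype=bool)
    for i, row in df.iterrows():
        rule = rules[row["source"]]
        ok = True
        if "grades" in rule:
            ok &= row["grade"] in set(rule["grades"])
        if "min_confidence" in rule:
            ok &= pd.notna(row["confidence"]) and row["confidence"] >= rule["min_confidence"]
        if "min_signal" in rule:
            ok &= pd.notna(row["signal"]) and row["signal"] >= rule["min_signal"]
        keep[i] = bool(ok)
    return df[keep].reset_index(drop=True)


def merge_sources(annotations, n_entities_total: int | None = None
                  ) -> tuple[pd.DataFrame, dict]:
    """Union per-source annotations into supported (entity, term) records.

    Returns the merged table with a ``sources`` set and ``support``
    count per (entity, term), plus a summary: entities covered, total
    merged annotations, support histogram, single-source and all-source
    fractions, and mean locations per annotated entity (and per entity
    overall when ``n_entities_total`` is given — the two readings of
    "average locations per entity").
    """
    df = _frame(annotations)
    n_sources = df["source"].nunique()
    merged = (df.groupby(["entity", "term"])["source"]
                .agg(lambda s: frozenset(s))
                .reset_index()
                .rename(columns={"source": "sources"}))
    merged["support"] = merged["sources"].map(len)
    if (merged["support"] > n_sources).any():
        raise AssertionError("support count exceeded source count")
    total = len(merged)
    hist = merged["support"].value_counts().sort_index().to_dict()
    summary = {
        "entities_covered": int(merged["entity"].nunique()),
        "total_annotations": int(total),
        "n_sources": int(n_sources),
        "support_histogram": {int(k): int(v) for k, v in hist.items()},
        "single_source_fraction": (hist.get(1, 0) / total) if total else 0.0,
        "all_source_fraction": (hist.get(n_sources, 0) / total) if total else 0.0,
        "mean_locations_per_annotated_entity":
            (total / merged["entity"].nunique()) if total else 0.0,
    }
    if n_entities_total:
        summary["mean_locations_per_entity"] = total / n_entities_total
    return merged, summary
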