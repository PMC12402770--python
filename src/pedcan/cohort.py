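"""Cohort utilities: gene-symbol liftover, expression-matrix collapse, and
independent-sample selection."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence

import pandas as pd

from .types import HistologyRecord

logger = logging.getLogger(__name__)


def liftover_symbols(
    table: pd.DataFrame, symbol_map: Mapping[str, str], columns: Sequence[str]
) -> pd.DataFrame:
    """Replace outdated gene symbols by their current HGNC symbol.

    Unknown symbols pass through unchanged; current symbols are fixed points.
    """
    out = table.copy()
    for col in columns:
        out[col] = out[col].map(lambda s: symbol_map.get(s, s))
    return out


def read_symbol_map(path) -> Dict[str, str]:
    """Load a two-column (prev_symbol, symbol) HGNC symbol-change TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"prev_symbol", "symbol"} <= set(df.columns):
        raise ValueError(f"symbol map {path} needs columns prev_symbol, symbol")
    return dict(zip(df["prev_symbol"], df["symbol"]))


def collapse_matrix(matrix: pd.DataFrame, symbol_col: str = "gene_symbol") -> pd.DataFrame:
    """Collapse an (Ensembl id x samples) matrix to unique gene symbols.

    Rows with all-zero expression are dropped first; among rows sharing a
    symbol, the one with the maximum mean value across samples is kept
    (ties broken by Ensembl-id sort order). The returned matrix is indexed
    by unique symbol.
    """
    if symbol_col not in matrix.columns:
        raise ValueError(f"matrix must carry a {symbol_col!r} column")
    values = matrix.drop(columns=[symbol_col])
    nonzero = values.sum(axis=1) > 0
    kept = matrix.loc[nonzero].copy()
    kept["_mean"] = values.loc[nonzero].mean(axis=1)
    kept = kept.sort_values("_mean", ascending=False)
    # stable selection: highest mean wins; equal means fall back to index sort
    kept = (
        kept.reset_index()
        .sort_values(["_mean", "index"], ascending=[False, True])
        .drop_duplicates(subset=symbol_col, keep="first")
        .set_index(symbol_col)
        .sort_index()
    )
    return kept.drop(columns=["index", "_mean"])


@dataclass
class IndependencePrefs:
    """Ordered preferences for selecting one biospecimen per participant.

    Earlier entries in each list are preferred; biospecimens whose value is
    absent from a list rank after all listed values. The final tie-break is
    the lexicographically smallest biospecimen id.
    """

    tumor_descriptors: Sequence[str] = (
        "Initial CNS Tumor",
        "Primary Tumor",
        "Progressive",
        "Recurrence",
    )
    experimental_strategies: Sequence[str] = ("WGS", "WXS", "Targeted", "RNA-Seq")


def select_independent(
    histologies: Sequence[HistologyRecord],
    prefs: IndependencePrefs | None = None,
    eligible=None,
) -> List[str]:
    """Pick exactly one biospecimen per participant, deterministically.

    ``eligible`` is an optional predicate filtering biospecimens before
    selection; participants with no eligible biospecimen are omitted with a
    log entry. The output is sorted by biospecimen id and invariant to
    input order.
    """
    prefs = prefs or IndependencePrefs()

    def rank(value, ordered):
        try:
            return ordered.index(value)
        except ValueError:
            return len(ordered)

    by_participant: Dict[str, List[HistologyRecord]] = {}
    for h in histologies:
        if eligible is not None and not eligible(h):
            continue
        by_participant.setdefault(h.participant_id, []).append(h)

    all_participants = {h.participant_id for h in histologies}
    for p in sorted(all_participants - set(by_participant)):
        logger.info("participant %s has no eligible biospecimen; omitted", p)

    chosen = []
    for p in sorted(by_participant):
        best = min(
            by_participant[p],
            key=lambda h: (
                rank(h.tumor_descriptor, prefs.tumor_descriptors),
                rank(h.experimental_strategy, prefs.experimental_strategies),
                h.biospecimen_id,
            ),
        )
        chosen.append(best.biospecimen_id)
    return sorted(chosen)
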