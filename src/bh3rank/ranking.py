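"""Best Priming Drug (BPD) and Response Difference (RD) ranking.

For a tumor × drug percent-priming matrix, the best priming drug of tumor i
is the drug (or drugs, under ties) maximizing priming:

    BPD_i = argmax_j priming(i, j)

and the response difference of every drug against that per-tumor best is

    RD(i, j) = priming(i, BPD_i) − priming(i, j)  ≥ 0.

Cohort summaries rank drugs: per-drug mean RD over all tumors (a drug that
is best everywhere has mean RD 0), BPD-conditional mean RD (restricted to
tumors whose best drug is a given reference drug), and BPD frequencies with
ties attributed fractionally so frequencies always sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class RankingResult:
    """Per-tumor BPD, RD matrix and cohort-level drug ranking summaries."""

    bpd: dict[str, frozenset[str]]     # tumor -> set of best drugs (ties kept)
    rd: pd.DataFrame                   # tumor × drug response difference
    avg_rd: pd.Series                  # per-drug mean RD over all tumors
    conditional_rd: pd.DataFrame       # rows: drug j, cols: reference drug;
                                       # mean RD(·, j) over tumors with ref ∈ BPD
    bpd_frequency: pd.Series           # fraction of tumors, ties split 1/|BPD|
    effective_n: pd.Series             # per-drug count of tumors entering avg_rd
    excluded_tumors: tuple[str, ...]   # tumors with no computable BPD

    @property
    def tumor_ids(self) -> list[str]:
        return list(self.rd.index)

    @property
    def drug_ids(self) -> list[str]:
        return list(self.rd.columns)

    def to_long(self, priming: pd.DataFrame) -> pd.DataFrame:
        """Long-format ``sample_id,drug,priming,rd,is_bpd`` table."""
        rows = []
        for sid in self.rd.index:
            best = self.bpd.get(sid, frozenset())
            for drug in self.rd.columns:
                rows.append(
                    {
                        "sample_id": sid,
                        "drug": drug,
                        "priming": priming.at[sid, drug] if sid in priming.index else np.nan,
                        "rd": self.rd.at[sid, drug],
                        "is_bpd": drug in best,
                    }
                )
        return pd.DataFrame(rows)


def best_priming_drug(priming: pd.DataFrame) -> dict[str, frozenset[str]]:
    """Per-tumor argmax of priming over drugs; ties return all maximizers.

    Missing entries are excluded from the argmax. A tumor whose entries are
    all missing gets an empty set (flagged; excluded from summaries).
    """
    if priming.shape[1] < 1:
        raise ValueError("priming matrix has no drug columns")
    out: dict[str, frozenset[str]] = {}
    for sid in priming.index:
        row = priming.loc[sid]
        if row.isna().all():
            out[sid] = frozenset()
            continue
        best = row.max(skipna=True)
        out[sid] = frozenset(row.index[row == best])
    return out


def response_difference(priming: pd.DataFrame) -> pd.DataFrame:
    """RD(i, j) = priming(i, BPD_i) − priming(i, j); missing stays missing."""
    row_max = priming.max(axis=1, skipna=True)
    rd = (-priming).add(row_max, axis=0)
    return rd


def summarize_ranking(
    rd: pd.DataFrame, bpd: dict[str, frozenset[str]]
) -> RankingResult:
    """Cohort-level drug ranking summaries from RD and per-tumor BPD.

    ``avg_rd`` averages over all tumors with a defined RD for the drug
    (pairwise deletion; the BPD itself contributes 0). ``conditional_rd``
    restricts to tumors whose BPD contains a given reference drug and is
    NaN (undefined, not zero) when that subset is empty. ``bpd_frequency``
    splits ties 1/|BPD| so the frequencies sum to 1 over drugs.
    """
    drugs = list(rd.columns)
    ranked_tumors = [t for t in rd.index if bpd.get(t)]
    excluded = tuple(t for t in rd.index if not bpd.get(t))
    rd_ranked = rd.loc[ranked_tumors]

    avg_rd = rd_ranked.mean(axis=0, skipna=True)
    effective_n = rd_ranked.notna().sum(axis=0)

    conditional = pd.DataFrame(np.nan, index=pd.Index(drugs, name="drug"),
                               columns=pd.Index(drugs, name="reference"))
    for ref in drugs:
        subset = [t for t in ranked_tumors if ref in bpd[t]]
        if not subset:
            continue
        conditional[ref] = rd_ranked.loc[subset].mean(axis=0, skipna=True)

    freq = pd.Series(0.0, index=pd.Index(drugs, name="drug"))
    for t in ranked_tumors:
        share = 1.0 / len(bpd[t])
        for d in bpd[t]:
            freq[d] += share
    if ranked_tumors:
        freq /= len(ranked_tumors)

    return RankingResult(
        bpd={t: bpd.get(t, frozenset()) for t in rd.index},
        rd=rd,
        avg_rd=avg_rd,
        conditional_rd=conditional,
        bpd_frequency=freq,
        effective_n=effective_n,
        excluded_tumors=excluded,
    )


def rank_drugs(priming: pd.DataFrame) -> RankingResult:
    """Full BPD/RD ranking of a tumor × drug priming matrix."""
    bpd = best_priming_drug(priming)
    rd = response_difference(priming)
    return summarize_ranking(rd, bpd)
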