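"""Relative expression from qPCR cycle-threshold (Ct) tables.

Implements comparative-Ct quantification: ΔCt against one or more reference
genes, ΔΔCt against the mean of designated normal (control) samples, and
RQ = 2^−ΔΔCt fold expression. Also provides the quartile-based Ct sensitivity
binning used to read resistance off raw Ct ranges, and per-sample
overexpressed-gene calls (Venn-style subset summaries).

Conventions
-----------
* Lower Ct means higher transcript abundance; a ΔΔCt decrease of 1 is a
  doubling of relative expression.
* Reference gene(s) and control (normal) samples are explicit, mandatory
  configuration. ΔCt uses the arithmetic mean Ct over reference genes.
* Missing Ct values propagate as missing (NaN); nothing is imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CT_MIN = 0.0
CT_MAX = 45.0

#: quartile index -> predicted response class (low Ct = high expression = resistance)
QUARTILE_CLASS = {
    1: "resistant-predicted",
    2: "moderate-predicted",
    3: "sensitive-predicted",
    4: "sensitive-predicted",
}


class FormatError(ValueError):
    """Malformed input table (bad header, non-numeric Ct, duplicate ids)."""


@dataclass
class CtTable:
    """Sample × gene matrix of qPCR cycle-threshold values plus metadata.

    Parameters
    ----------
    ct : DataFrame
        Index = sample ids, columns = gene ids, values = Ct in cycles
        (NaN marks missing wells).
    roles : Series
        Per-sample role, ``"tumor"`` or ``"normal"``.
    reference_genes : tuple of str
        Genes used as the ΔCt normalizer; must be a subset of the columns.
    metadata : DataFrame, optional
        Per-sample covariates (e.g. ``gender``, ``grade``).
    """

    ct: pd.DataFrame
    roles: pd.Series
    reference_genes: tuple[str, ...]
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.reference_genes = tuple(self.reference_genes)
        if self.ct.index.has_duplicates:
            dups = self.ct.index[self.ct.index.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        if not self.reference_genes:
            raise FormatError("at least one reference gene is required")
        missing_ref = set(self.reference_genes) - set(self.ct.columns)
        if missing_ref:
            raise FormatError(f"reference genes not in table: {sorted(missing_ref)}")
        bad_roles = set(self.roles.unique()) - {"tumor", "normal"}
        if bad_roles:
            raise FormatError(f"unknown sample roles: {sorted(bad_roles)}")
        vals = self.ct.to_numpy(dtype=float)
        finite = np.isfinite(vals)
        if np.isinf(vals).any():
            raise FormatError("infinite Ct values are not allowed")
        out_of_range = finite & ((vals <= CT_MIN) | (vals > CT_MAX))
        if out_of_range.any():
            i, j = np.argwhere(out_of_range)[0]
            raise FormatError(
                f"Ct out of range (0, {CT_MAX}] for sample "
                f"{self.ct.index[i]!r}, gene {self.ct.columns[j]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ct.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def target_genes(self) -> list[str]:
        return [g for g in self.ct.columns if g not in self.reference_genes]

    @property
    def tumor_ids(self) -> list[str]:
        return list(self.roles.index[self.roles == "tumor"])

    @property
    def normal_ids(self) -> list[str]:
        return list(self.roles.index[self.roles == "normal"])


@dataclass
class ExpressionTable:
    """ΔΔCt and RQ (= 2^−ΔΔCt) values per sample × target gene."""

    ddct: pd.DataFrame
    rq: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ddct.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.ddct.columns)

    def to_long(self) -> pd.DataFrame:
        """Long-format ``sample_id, gene, ddct, rq`` table."""
        d = self.ddct.stack(future_stack=True).rename("ddct")
        r = self.rq.stack(future_stack=True).rename("rq")
        out = pd.concat([d, r], axis=1).reset_index()
        out.columns = ["sample_id", "gene", "ddct", "rq"]
        return out


@dataclass
class QuartileBinning:
    """Quartile assignment of tumor Ct values for one gene."""

    gene: str
    boundaries: tuple[float, float, float, float, float]
    assignment: pd.Series  # tumor -> quartile index 1..4 (NaN-missing tumors absent)
    predicted_class: pd.Series  # tumor -> predicted response class

    def counts(self) -> pd.Series:
        return self.assignment.value_counts().reindex([1, 2, 3, 4], fill_value=0)


@dataclass(frozen=True)
class OverexpressionCalls:
    """Per-sample overexpressed gene sets and Venn-region counts."""

    calls: dict[str, frozenset[str]]
    fold_threshold: float
    genes: tuple[str, ...]
    venn_counts: dict[frozenset, int] = field(repr=False, default_factory=dict)


def read_ct_table(
    path,
    reference_genes: tuple[str, ...] | list[str],
    metadata_columns: tuple[str, ...] = ("gender", "grade"),
) -> CtTable:
    """Read a ``ct_table.csv`` file.

    Expected header: ``sample_id,role,gender,grade,<gene1>,...`` with
    role in {tumor, normal} and Ct as decimal (``NA``/empty = missing).
    """
    df = pd.read_csv(path, dtype=str)
    required = ["sample_id", "role", *metadata_columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    gene_cols = [c for c in df.columns if c not in required]
    if not gene_cols:
        raise FormatError(f"{path}: no gene columns found")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"{path}: duplicate sample ids {dups}")
    ct = pd.DataFrame(index=pd.Index(df["sample_id"], name="sample_id"))
    for g in gene_cols:
        col = df[g].replace({"NA": np.nan, "": np.nan})
        try:
            ct[g] = pd.to_numeric(col).to_numpy()
        except (ValueError, TypeError) as exc:
            bad = df.loc[pd.to_numeric(col, errors="coerce").isna() & col.notna()]
            row = bad["sample_id"].iloc[0] if len(bad) else "?"
            raise FormatError(
                f"{path}: non-numeric Ct in column {g!r}, sample {row!r}"
            ) from exc
    roles = pd.Series(df["role"].to_numpy(), index=ct.index, name="role")
    metadata = pd.DataFrame(
        {c: df[c].to_numpy() for c in metadata_columns}, index=ct.index
    )
    return CtTable(ct=ct, roles=roles, reference_genes=tuple(reference_genes), metadata=metadata)


def write_ct_table(table: CtTable, path) -> None:
    """Write a :class:`CtTable` in the ``ct_table.csv`` dialect."""
    out = pd.DataFrame(index=table.ct.index)
    out["role"] = table.roles
    meta = table.metadata if table.metadata is not None else pd.DataFrame(index=table.ct.index)
    for c in ("gender", "grade"):
        out[c] = meta[c] if c in meta.columns else ""
    for g in table.gene_ids:
        out[g] = table.ct[g]
    out.to_csv(path, index=True, index_label="sample_id", na_rep="NA")


def delta_delta_ct(ct: CtTable) -> ExpressionTable:
    """Comparative-Ct relative quantification.

    ΔCt(s, g) = Ct(s, g) − mean over reference genes of Ct(s, ref);
    ΔΔCt(s, g) = ΔCt(s, g) − mean over normal samples of ΔCt(normal, g);
    RQ = 2^−ΔΔCt. Normal samples are normalized against the same control
    mean, so with a single control sample its RQ is exactly 1 per gene.
    """
    if not ct.normal_ids:
        raise ValueError("ΔΔCt requires at least one sample with role 'normal'")
    ref = ct.ct[list(ct.reference_genes)].mean(axis=1, skipna=True)
    all_ref_missing = ref.isna()
    if all_ref_missing.any():
        warnings.warn(
            "all reference-gene Ct missing for sample(s) "
            f"{list(ct.ct.index[all_ref_missing])}; their ΔΔCt is flagged missing",
            stacklevel=2,
        )
    targets = ct.target_genes
    dct = ct.ct[targets].sub(ref, axis=0)
    control_mean = dct.loc[ct.normal_ids].mean(axis=0, skipna=True)
    ddct = dct.sub(control_mean, axis=1)
    rq = np.power(2.0, -ddct)
    return ExpressionTable(ddct=ddct, rq=rq)


def quartile_classes(
    ct: CtTable,
    gene: str,
    boundaries: tuple[float, ...] | None = None,
) -> QuartileBinning:
    """Assign tumors to Ct quartiles for one gene and predict response.

    Quartile 1 holds the lowest Ct (highest expression) tumors and maps to
    ``resistant-predicted``; quartile 2 to ``moderate-predicted``; quartiles
    3–4 to ``sensitive-predicted``. A Ct equal to an interior boundary joins
    the lower-Ct quartile, matching contiguous printed ranges such as
    19–23 / 23–26 where the shared endpoint belongs to the lower range.
    """
    if gene not in ct.gene_ids:
        raise KeyError(f"gene {gene!r} not in Ct table")
    values = ct.ct.loc[ct.tumor_ids, gene].dropna()
    if boundaries is None:
        if values.nunique() < 4:
            raise ValueError(
                f"fewer than 4 distinct Ct values for {gene!r}; "
                "pass explicit boundaries"
            )
        q1, q2, q3 = np.percentile(values.to_numpy(), [25, 50, 75])
        boundaries = (float(values.min()), float(q1), float(q2), float(q3), float(values.max()))
    boundaries = tuple(float(b) for b in boundaries)
    if len(boundaries) != 5 or any(
        b1 > b2 for b1, b2 in zip(boundaries, boundaries[1:])
    ):
        raise ValueError("boundaries must be 5 ascending Ct values")
    interior = np.asarray(boundaries[1:4])
    # searchsorted(side="left"): value == interior boundary -> lower quartile
    q = np.searchsorted(interior, values.to_numpy(), side="left") + 1
    assignment = pd.Series(q, index=values.index, name="quartile")
    predicted = assignment.map(QUARTILE_CLASS).rename("predicted_class")
    return QuartileBinning(
        gene=gene,
        boundaries=boundaries,  # type: ignore[arg-type]
        assignment=assignment,
        predicted_class=predicted,
    )


def call_overexpressed(
    expr: ExpressionTable,
    fold_threshold: float = 2.0,
    genes: list[str] | None = None,
) -> OverexpressionCalls:
    """Call gene g overexpressed in sample s iff RQ(s, g) ≥ fold_threshold.

    Missing RQ values are never called. ``venn_counts`` maps each realized
    gene subset (Venn region) to the number of samples whose called set is
    exactly that subset.
    """
    if fold_threshold <= 0:
        raise ValueError("fold_threshold must be positive")
    genes = list(expr.gene_ids) if genes is None else list(genes)
    rq = expr.rq[genes]
    calls: dict[str, frozenset[str]] = {}
    for s in rq.index:
        row = rq.loc[s]
        calls[s] = frozenset(g for g in genes if pd.notna(row[g]) and row[g] >= fold_threshold)
    venn: dict[frozenset, int] = {}
    for called in calls.values():
        venn[called] = venn.get(called, 0) + 1
    return OverexpressionCalls(
        calls=calls,
        fold_threshold=float(fold_threshold),
        genes=tuple(genes),
        venn_counts=venn,
    )
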