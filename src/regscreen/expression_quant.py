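"""Relative expression from qPCR threshold cycles by the 2^−ΔΔCT method.

Each replicate's target-gene Ct is first normalized within its strain
against a stably expressed reference gene (ΔCt = Ct_gene − Ct_ref; the
*Streptomyces* convention is the principal sigma-factor gene *hrdB*).  The
test strain is then compared with the control strain on the ΔCt scale
(ΔΔCt = mean ΔCt_test − mean ΔCt_control) and the fold change is
2^−ΔΔCt, with the control strain's expression defined as 1.0.

Statistics are computed on the ΔCt scale, where replicate noise is
approximately normal: the replicate SDs of the two strains are pooled in
quadrature and propagated into an asymmetric fold range 2^−(ΔΔCt ± SD);
significance is a two-sided Welch t-test on the two ΔCt replicate sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("strain", "gene", "replicate", "Ct")


class CtTableError(ValueError):
    """Raised for malformed or insufficient Ct data."""


@dataclass
class CtTable:
    """Replicate qPCR threshold-cycle measurements."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise CtTableError(f"Ct table missing columns: {missing}")
        if (self.data["Ct"] <= 0).any():
            raise CtTableError("Ct values must be positive")

    @classmethod
    def from_csv(cls, path: str | Path, sep: str | None = None) -> "CtTable":
        if sep is None:
            sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        return cls(pd.read_csv(path, sep=sep))

    def ct_values(self, strain: str, gene: str) -> pd.Series:
        sub = self.data[(self.data["strain"] == strain) & (self.data["gene"] == gene)]
        return sub.set_index("replicate")["Ct"]

    def delta_ct(self, strain: str, gene: str, reference: str) -> np.ndarray:
        """Per-replicate ΔCt = Ct_gene − Ct_reference within one strain."""
        g = self.ct_values(strain, gene)
        r = self.ct_values(strain, reference)
        if g.empty:
            raise CtTableError(f"no Ct values for gene {gene!r} in strain {strain!r}")
        if r.empty:
            raise CtTableError(
                f"reference gene {reference!r} not measured in strain {strain!r}"
            )
        paired = pd.concat([g.rename("gene"), r.rename("ref")], axis=1).dropna()
        if len(paired) < 2:
            raise CtTableError(
                f"need >= 2 paired replicates for {gene!r} vs {reference!r} "
                f"in strain {strain!r}, got {len(paired)}"
            )
        return (paired["gene"] - paired["ref"]).to_numpy()


@dataclass(frozen=True)
class FoldChange:
    """A 2^−ΔΔCt relative-expression result for one gene and strain pair."""

    gene: str
    test_strain: str
    control_strain: str
    ddct_mean: float
    fold: float
    fold_sd_range: tuple[float, float]
    p_value: float

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def significance_stars(p: float) -> str:
    """Figure-legend star convention: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def delta_delta_ct(
    table: CtTable,
    gene: str,
    test: str,
    reference: str = "hrdB",
    control: str = "WT",
) -> FoldChange:
    """Fold change of ``gene`` in ``test`` relative to ``control``, as 2^−ΔΔCt.

    The reference gene requested as target yields fold 1 with a warning.
    Missing measurements or fewer than two paired replicates raise
    :class:`CtTableError` naming the gap.
    """
    if gene == reference:
        warnings.warn(
            f"target gene equals the reference gene {reference!r}; fold is 1 by construction"
        )
    dct_test = table.delta_ct(test, gene, reference)
    dct_control = table.delta_ct(control, gene, reference)
    ddct = float(np.mean(dct_test) - np.mean(dct_control))
    fold = float(2.0 ** (-ddct))
    sd_pooled = float(np.sqrt(np.var(dct_test, ddof=1) + np.var(dct_control, ddof=1)))
    lo = float(2.0 ** (-(ddct + sd_pooled)))
    hi = float(2.0 ** (-(ddct - sd_pooled)))
    if np.allclose(dct_test, dct_test[0]) and np.allclose(dct_control, dct_control[0]):
        p = 0.0 if not np.isclose(ddct, 0.0) else 1.0  # degenerate zero-variance case
    else:
        p = float(stats.ttest_ind(dct_test, dct_control, equal_var=False).pvalue)
    return FoldChange(
        gene=gene,
        test_strain=test,
        control_strain=control,
        ddct_mean=ddct,
        fold=fold,
        fold_sd_range=(lo, hi),
        p_value=p,
    )


def fold_change_report(
    table: CtTable,
    genes: Sequence[str],
    test_strains: Sequence[str],
    reference: str = "hrdB",
    control: str = "WT",
    skip_missing: bool = True,
) -> pd.DataFrame:
    """One fold-change row per (gene, test strain), with significance stars.

    Genes undetectable in a strain (missing Ct rows) are skipped with a
    warning when ``skip_missing``; set it False to raise instead.
    """
    rows = []
    for strain in test_strains:
        for gene in genes:
            try:
                fc = delta_delta_ct(table, gene, strain, reference=reference, control=control)
            except CtTableError as exc:
                if skip_missing:
                    warnings.warn(f"skipping {gene!r} in {strain!r}: {exc}")
                    continue
                raise
            rows.append(
                {
                    "gene": fc.gene,
                    "test_strain": fc.test_strain,
                    "control_strain": fc.control_strain,
                    "ddct": fc.ddct_mean,
                    "fold": fc.fold,
                    "fold_low": fc.fold_sd_range[0],
                    "fold_high": fc.fold_sd_range[1],
                    "p_value": fc.p_value,
                    "significance": fc.stars,
                }
            )
    return pd.DataFrame(rows)
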