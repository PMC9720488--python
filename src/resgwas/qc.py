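"""SNP quality-control cascade for the genotype panel.

Three steps, applied in order:

1. discard SNPs with more than 10% missing calls (strict inequality);
2. per SNP, set every genotype class with fewer than 10 individuals to
   missing; on the Z chromosome additionally mask all heterozygous calls
   (the analysed individuals are hemizygous females, so a Z heterozygote
   is a genotyping artefact);
3. discard SNPs left with fewer than two genotype classes of at least 10
   individuals (no analysable contrast for a categorical SNP effect).

The cascade is idempotent and preserves SNP order; the report's counts
close exactly: input = retained + dropped(missingness) + dropped(classes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import MISSING_CALL, GenotypePanel

__all__ = [
    "QcReport",
    "genotype_class_counts",
    "filter_missingness",
    "mask_rare_classes",
    "drop_underfilled_snps",
    "qc_pipeline",
]

MAX_MISSING = 0.10
MIN_CLASS_COUNT = 10


@dataclass
class QcReport:
    n_input_snps: int = 0
    n_dropped_missingness: int = 0
    n_dropped_class_rule: int = 0
    n_retained: int = 0
    n_masked_rare_class_calls: int = 0
    n_masked_z_het_calls: int = 0
    dropped_missingness: list[str] = field(default_factory=list)
    dropped_class_rule: list[str] = field(default_factory=list)
    class_counts_before: pd.DataFrame | None = None
    class_counts_after: pd.DataFrame | None = None

    def check(self) -> None:
        total = self.n_retained + self.n_dropped_missingness + self.n_dropped_class_rule
        if total != self.n_input_snps:
            raise AssertionError(
                f"QC report does not close: {self.n_input_snps} != {total}"
            )

    def to_dict(self) -> dict:
        return {
            "n_input_snps": self.n_input_snps,
            "n_dropped_missingness": self.n_dropped_missingness,
            "n_dropped_class_rule": self.n_dropped_class_rule,
            "n_retained": self.n_retained,
            "n_masked_rare_class_calls": self.n_masked_rare_class_calls,
            "n_masked_z_het_calls": self.n_masked_z_het_calls,
        }


def genotype_class_counts(panel: GenotypePanel) -> pd.DataFrame:
    """Per-SNP counts of the 0/1/2 genotype classes (missing excluded)."""
    counts = {g: (panel.calls == g).sum(axis=0) for g in (0, 1, 2)}
    return pd.DataFrame(counts, index=panel.snp_map["snp_id"].to_numpy())


def filter_missingness(
    panel: GenotypePanel, max_missing: float = MAX_MISSING
) -> tuple[GenotypePanel, list[str]]:
    """Drop SNPs whose missing-call fraction strictly exceeds ``max_missing``."""
    if panel.n_snps == 0 or panel.n_individuals == 0:
        raise ValueError("empty genotype panel")
    frac = (panel.calls == MISSING_CALL).mean(axis=0)
    keep = frac <= max_missing
    dropped = panel.snp_map.loc[~keep, "snp_id"].tolist()
    return panel.subset_snps(keep), dropped


def mask_rare_classes(
    panel: GenotypePanel, min_count: int = MIN_CLASS_COUNT
) -> tuple[GenotypePanel, int, int]:
    """Set calls of genotype classes with fewer than ``min_count``
    individuals to missing; on Z, mask heterozygotes unconditionally.

    Returns the masked panel and the numbers of rare-class and
    Z-heterozygote calls masked.
    """
    calls = panel.calls.copy()
    is_z = panel.is_z
    n_z_het = 0
    if is_z.any():
        zcols = np.flatnonzero(is_z)
        het = calls[:, zcols] == 1
        n_z_het = int(het.sum())
        sub = calls[:, zcols]
        sub[het] = MISSING_CALL
        calls[:, zcols] = sub
    n_rare = 0
    for g in (0, 1, 2):
        is_g = calls == g
        rare = is_g.sum(axis=0) < min_count
        mask = is_g & rare[None, :]
        n_rare += int(mask.sum())
        calls[mask] = MISSING_CALL
    out = GenotypePanel(list(panel.ids), panel.snp_map.copy(), calls)
    return out, n_rare, n_z_het


def drop_underfilled_snps(
    panel: GenotypePanel, min_count: int = MIN_CLASS_COUNT
) -> tuple[GenotypePanel, list[str]]:
    """Drop SNPs with fewer than two genotype classes of at least
    ``min_count`` individuals (assumes rare classes already masked).

    For Z-SNPs only two classes exist to begin with; the criterion is the
    same: at least two analysable classes.
    """
    counts = genotype_class_counts(panel).to_numpy()
    keep = (counts >= min_count).sum(axis=1) >= 2
    dropped = panel.snp_map.loc[~keep, "snp_id"].tolist()
    return panel.subset_snps(keep), dropped


def qc_pipeline(
    panel: GenotypePanel,
    max_missing: float = MAX_MISSING,
    min_count: int = MIN_CLASS_COUNT,
) -> tuple[GenotypePanel, QcReport]:
    """Missingness filter, then rare-class/Z-het masking, then the
    two-class discard rule; emits a closing report."""
    report = QcReport(n_input_snps=panel.n_snps)
    report.class_counts_before = genotype_class_counts(panel)

    panel1, dropped_miss = filter_missingness(panel, max_missing)
    report.dropped_missingness = dropped_miss
    report.n_dropped_missingness = len(dropped_miss)

    panel2, n_rare, n_z_het = mask_rare_classes(panel1, min_count)
    report.n_masked_rare_class_calls = n_rare
    report.n_masked_z_het_calls = n_z_het

    panel3, dropped_class = drop_underfilled_snps(panel2, min_count)
    report.dropped_class_rule = dropped_class
    report.n_dropped_class_rule = len(dropped_class)
    report.n_retained = panel3.n_snps
    report.class_counts_after = genotype_class_counts(panel3)
    report.check()
    return panel3, report
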