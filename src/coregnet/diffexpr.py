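"""Differential-expression calls between carbon sources and Venn set logic.

Genes are called differentially expressed when both threshold criteria hold:
(1) linear fold change ≥ 1.5 in either direction, i.e. |log2 fold change| ≥
log2(1.5), and (2) p ≤ 0.05 from a two-sided two-sample t-test on replicate
log2 values. Both thresholds are inclusive and configurable via
:class:`DEConfig`.

The test is pluggable: the default is the pooled-variance Student t, which
is exactly calibrated for equal-variance log-scale replicates at triplicate
sample sizes; Welch's unequal-variance t is available via
``method="welch"`` but is noticeably conservative at n = 3 per group
(its Satterthwaite degrees-of-freedom approximation undershoots the nominal
level by roughly a third there).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from coregnet.preprocessing import ExpressionDataset, InputError

UP_IN_A = "up_in_A"
UP_IN_B = "up_in_B"
NONE = "none"


@dataclass
class DEConfig:
    """Thresholds for differential-expression calling.

    ``fc_threshold`` is a linear fold change (default 1.5, applied
    symmetrically in both directions); ``alpha`` the p-value cutoff.
    ``adjust`` switches on Benjamini–Hochberg correction of the p-values
    before thresholding (off by default: the calls mirror raw-p criteria).
    """

    fc_threshold: float = 1.5
    alpha: float = 0.05
    adjust: bool = False

    def __post_init__(self) -> None:
        if self.fc_threshold < 1:
            raise InputError(f"fc_threshold must be ≥ 1, got {self.fc_threshold}")
        if not 0 < self.alpha <= 1:
            raise InputError(f"alpha must be in (0, 1], got {self.alpha}")

    @property
    def log2fc_threshold(self) -> float:
        return float(np.log2(self.fc_threshold))


@dataclass
class DETable:
    """Per-gene log2 fold change, p-value and up/down/none call for one contrast.

    ``table`` is indexed by gene ID with columns ``log2fc`` (mean log2 of
    condition A minus condition B), ``p_value``, and ``call`` in
    {``up_in_A``, ``up_in_B``, ``none``}.
    """

    table: pd.DataFrame
    contrast: tuple[str, str]
    config: DEConfig

    @property
    def up_in_a(self) -> set[str]:
        return set(self.table.index[self.table["call"] == UP_IN_A])

    @property
    def up_in_b(self) -> set[str]:
        return set(self.table.index[self.table["call"] == UP_IN_B])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


def classify_de(log2fc: float, p_value: float, cfg: DEConfig) -> str:
    """Assign the up/down/none call for one gene (inclusive thresholds).

    The fold-change comparison carries a 1e-9 absolute tolerance so that a
    gene sitting exactly on the threshold is called even when averaging the
    replicate values loses the last bits of the boundary.
    """
    if p_value <= cfg.alpha and abs(log2fc) >= cfg.log2fc_threshold - 1e-9:
        return UP_IN_A if log2fc > 0 else UP_IN_B
    return NONE


def de_test(
    ds: ExpressionDataset,
    contrast: tuple[str, str],
    cfg: DEConfig | None = None,
    species: str | None = None,
    method: str = "student",
) -> DETable:
    """Two-sample t-test per gene between two conditions.

    ``ds`` must be log2-scale. log2fc is the mean log2 value in condition A
    minus condition B; the p-value is two-sided, from the pooled-variance
    Student t by default (``method="welch"`` for the unequal-variance
    test). When both replicate groups have zero variance the t-statistic is
    undefined and the degenerate rule applies: p = 1 if the group means are
    equal, else p = 0.
    """
    cfg = cfg or DEConfig()
    if not ds.log_scale:
        raise InputError("de_test expects a log2-transformed dataset")
    if method not in ("student", "welch"):
        raise InputError(f"method must be 'student' or 'welch', got {method!r}")
    cond_a, cond_b = contrast
    cols_a = ds.columns_for(species=species, condition=cond_a)
    cols_b = ds.columns_for(species=species, condition=cond_b)
    for cond, cols in ((cond_a, cols_a), (cond_b, cols_b)):
        if not cols:
            raise InputError(f"condition {cond!r} not present in dataset")
        if len(cols) < 2:
            raise InputError(f"condition {cond!r} has fewer than 2 replicates")
    a = ds.values[cols_a].to_numpy(dtype=float)
    b = ds.values[cols_b].to_numpy(dtype=float)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-constant rows warn about precision loss; the degenerate rule
        # below overrides their p-values anyway
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=(method == "student"))
    p = np.asarray(p, dtype=float)
    # both-variances-zero rows yield nan; apply the degenerate rule
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p[degenerate] = np.where(log2fc[degenerate] == 0, 1.0, 0.0)
    p = np.clip(p, 0.0, 1.0)
    p_for_call = p
    if cfg.adjust:
        p_for_call = stats.false_discovery_control(p, method="bh")
    calls = [classify_de(fc, pv, cfg) for fc, pv in zip(log2fc, p_for_call)]
    table = pd.DataFrame(
        {"log2fc": log2fc, "p_value": p, "call": calls}, index=ds.values.index
    )
    return DETable(table=table, contrast=(cond_a, cond_b), config=cfg)


def de_summary(table: DETable) -> dict[str, int]:
    """Counts of up-in-A, up-in-B and unchanged genes; sums to the gene total."""
    counts = table.table["call"].value_counts()
    return {
        UP_IN_A: int(counts.get(UP_IN_A, 0)),
        UP_IN_B: int(counts.get(UP_IN_B, 0)),
        NONE: int(counts.get(NONE, 0)),
    }


def venn(sets: dict[str, set]) -> dict[tuple[str, ...], set]:
    """Partition the union of 2–4 named sets into Venn regions.

    Returns a mapping from region signature — the sorted tuple of set names
    an element belongs to — to the elements exclusive to that region. All
    2^k − 1 signatures are present (possibly empty), and every input
    element appears in exactly one region.
    """
    if not 2 <= len(sets) <= 4:
        raise InputError(f"venn supports 2–4 sets, got {len(sets)}")
    names = sorted(sets)
    regions: dict[tuple[str, ...], set] = {}
    for mask in range(1, 2 ** len(names)):
        sig = tuple(n for i, n in enumerate(names) if mask >> i & 1)
        regions[sig] = set()
    for elem in set().union(*sets.values()):
        sig = tuple(n for n in names if elem in sets[n])
        regions[sig].add(elem)
    return regions


def venn_to_frame(regions: dict[tuple[str, ...], set]) -> pd.DataFrame:
    """Tabulate Venn regions as (region, n, ids) rows for TSV export."""
    rows = [
        ("&".join(sig), len(members), ",".join(sorted(map(str, members))))
        for sig, members in sorted(regions.items(), key=lambda kv: (len(kv[0]), kv[0]))
    ]
    return pd.DataFrame(rows, columns=["region", "n", "ids"])
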