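"""Disruptive-indel odds ratios from sorted-bin amplicon sequencing.

Cells engineered at a putative regulatory site are FACS-sorted into
low- and high-expression bins and amplicon-sequenced; each allele
carries a compact indel descriptor (e.g. ``-16:32D`` = 32 bp deletion
at offset -16).  An allele is *disruptive* when any single indel
operation exceeds ``min_indel`` (3 bp by default, strictly greater).
Reads are aggregated into a 2x2 table by (disruptive, bin) and the
association between disruption and low expression is the odds ratio

    OR = (disruptive_low / nondisruptive_low)
       / (disruptive_high / nondisruptive_high)

whose log has the closed-form Wald standard error
sqrt(1/a + 1/b + 1/c + 1/d); this coincides with the grouped logistic
regression estimate for a saturated 2x2 model.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

_OP_RE = re.compile(r"^(-?\d+):(\d+)([DI])$")
_NOOP_TOKENS = {"", "WT", "SNV", "NA"}


class IndelParseError(ValueError):
    pass


@dataclass(frozen=True)
class IndelOp:
    kind: str  # "D" or "I"
    length: int
    offset: int


@dataclass
class IndelORResult:
    disruptive_low: float
    nondisruptive_low: float
    disruptive_high: float
    nondisruptive_high: float
    or_estimate: float
    ci_low: float
    ci_high: float
    beta: float
    se: float
    haldane_applied: bool = False

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def parse_ops(descriptor: str, allele_id: str = "?") -> list[IndelOp]:
    """Parse a comma-separated op descriptor.

    Tokens: ``<offset>:<len>D`` (deletion), ``<offset>:<len>I``
    (insertion), or ``WT``/``SNV`` for alleles with no indel.
    """
    descriptor = str(descriptor).strip()
    if descriptor in _NOOP_TOKENS:
        return []
    ops = []
    for token in descriptor.split(","):
        token = token.strip()
        if token in _NOOP_TOKENS:
            continue
        m = _OP_RE.match(token)
        if not m:
            raise IndelParseError(f"allele {allele_id}: malformed op {token!r}")
        offset, length, kind = int(m.group(1)), int(m.group(2)), m.group(3)
        ops.append(IndelOp(kind=kind, length=length, offset=offset))
    return ops


def max_indel_length(descriptor: str, allele_id: str = "?") -> int:
    ops = parse_ops(descriptor, allele_id)
    return max((op.length for op in ops), default=0)


def classify_alleles(
    table: pd.DataFrame, min_indel: int = 3
) -> tuple[pd.Series, tuple[int, int, int, int]]:
    """Flag disruptive alleles and tally reads into the 2x2 cells.

    An allele is disruptive iff any single insertion or deletion is
    strictly longer than ``min_indel`` bp.  Accepts the wide dialect
    (``reads_low``/``reads_high`` columns) or a long dialect with
    ``bin`` in {low, high} and ``reads``.  Returns the per-allele flag
    and (disruptive_low, nondisruptive_low, disruptive_high,
    nondisruptive_high).
    """
    if "bin" in table.columns and "reads" in table.columns:
        wide = table.pivot_table(
            index=["allele_id", "ops"], columns="bin", values="reads", aggfunc="sum"
        ).reset_index()
        wide = wide.rename(columns={"low": "reads_low", "high": "reads_high"}).fillna(0)
        table = wide
    required = {"allele_id", "ops", "reads_low", "reads_high"}
    if not required.issubset(table.columns):
        raise IndelParseError(f"allele table needs columns {sorted(required)}")

    flags = pd.Series(
        [
            max_indel_length(ops, aid) > min_indel
            for aid, ops in zip(table["allele_id"], table["ops"])
        ],
        index=table.index,
        name="disruptive",
    )
    dl = int(table.loc[flags, "reads_low"].sum())
    dh = int(table.loc[flags, "reads_high"].sum())
    ndl = int(table.loc[~flags, "reads_low"].sum())
    ndh = int(table.loc[~flags, "reads_high"].sum())
    return flags, (dl, ndl, dh, ndh)


def disruption_or(
    cells: tuple[float, float, float, float],
    haldane: bool = False,
    conf_level: float = 0.95,
) -> IndelORResult:
    """Disruption odds ratio with the Wald confidence interval.

    ``cells`` = (disruptive_low, nondisruptive_low, disruptive_high,
    nondisruptive_high) read counts.  A zero cell is an error unless
    ``haldane=True`` adds 0.5 to every cell first.
    """
    dl, ndl, dh, ndh = (float(c) for c in cells)
    if min(dl, ndl, dh, ndh) < 0:
        raise ValueError("read counts must be non-negative")
    applied = False
    if 0.0 in (dl, ndl, dh, ndh):
        if not haldane:
            raise ValueError(
                "zero cell in the 2x2 table; pass haldane=True to apply the +0.5 correction"
            )
        dl, ndl, dh, ndh = dl + 0.5, ndl + 0.5, dh + 0.5, ndh + 0.5
        applied = True
    beta = float(np.log((dl / ndl) / (dh / ndh)))
    se = float(np.sqrt(1 / dl + 1 / ndl + 1 / dh + 1 / ndh))
    zcrit = float(norm.ppf(0.5 + conf_level / 2))
    return IndelORResult(
        disruptive_low=dl,
        nondisruptive_low=ndl,
        disruptive_high=dh,
        nondisruptive_high=ndh,
        or_estimate=float(np.exp(beta)),
        ci_low=float(np.exp(beta - zcrit * se)),
        ci_high=float(np.exp(beta + zcrit * se)),
        beta=beta,
        se=se,
        haldane_applied=applied,
    )


def irls_log_odds_ratio(
    cells: tuple[float, float, float, float],
    tol: float = 1e-12,
    max_iter: int = 50,
) -> float:
    """Grouped logistic regression of bin (low vs high) on the
    disruptive indicator, fit by iteratively reweighted least squares.

    For the saturated 2x2 model the slope equals the log cross-product
    odds ratio; retained as an internal cross-check of
    :func:`disruption_or`.
    """
    dl, ndl, dh, ndh = (float(c) for c in cells)
    # rows: disruptive, non-disruptive; successes = low-bin reads
    y = np.array([dl, ndl])
    n = np.array([dl + dh, ndl + ndh])
    x = np.column_stack([np.ones(2), np.array([1.0, 0.0])])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = x @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = n * mu * (1.0 - mu)
        z = eta + (y - n * mu) / w
        wx = x * w[:, None]
        new = np.linalg.solve(x.T @ wx, wx.T @ z)
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    return float(beta[1])
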