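"""Manual-vs-automatic census error typology and summary statistics.

Each evaluated frame carries a manual fish count N and an automatic count M.
The pair is assigned to exactly one of seven mutually exclusive categories:

* ``Correct0``        - no fish manually, none automatically (N = M = 0)
* ``CorrectN``        - fish present and the counts agree (N = M > 0)
* ``Img0-ClassN``     - empty frame scored as containing fish (N = 0, M > 0)
* ``ImgN-Class0``     - fish present but none detected (N > 0, M = 0)
* ``ImgN-ClassM``     - fish present, counts disagree (generic miscount)
* ``Img>20-Class<10`` - a school (N > 20) scored as fewer than 10
* ``Img<10-Class>20`` - few fish (N < 10) scored as more than 20

The school-confusion rules outrank the generic zero-detection rule: a school
frame in which the automatic method found nothing (N > 20, M = 0) is a school
failure, not an ``ImgN-Class0`` case.  This is the ordering under which the
category tallies, the with-fish frame counts and the reported percentages of
the reference evaluation are mutually consistent.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

SCHOOL_THRESHOLD = 20  # a manual count above this is a school
LOW_THRESHOLD = 10  # "few fish" bound used by the school-confusion rules


class ValidationError(ValueError):
    pass


class ErrorCategory(str, Enum):
    """The seven mutually exclusive manual-vs-automatic outcome classes."""

    CORRECT0 = "Correct0"
    CORRECTN = "CorrectN"
    IMG0_CLASSN = "Img0-ClassN"
    IMGN_CLASS0 = "ImgN-Class0"
    IMGN_CLASSM = "ImgN-ClassM"
    IMG_GT20_CLASS_LT10 = "Img>20-Class<10"
    IMG_LT10_CLASS_GT20 = "Img<10-Class>20"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Fixed rendering order for tables (matches the reference layout).
CATEGORY_ORDER = (
    ErrorCategory.CORRECT0,
    ErrorCategory.CORRECTN,
    ErrorCategory.IMG0_CLASSN,
    ErrorCategory.IMGN_CLASS0,
    ErrorCategory.IMGN_CLASSM,
    ErrorCategory.IMG_GT20_CLASS_LT10,
    ErrorCategory.IMG_LT10_CLASS_GT20,
)


@dataclass(frozen=True)
class CountPair:
    """Manual count N and automatic count M for one image."""

    image_id: str
    N: int
    M: int

    def __post_init__(self) -> None:
        for name, v in (("N", self.N), ("M", self.M)):
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")


def classify_pair(
    pair: CountPair,
    school_threshold: int = SCHOOL_THRESHOLD,
    low_threshold: int = LOW_THRESHOLD,
    school_rule: str = "label",
) -> ErrorCategory:
    """Assign a (N, M) pair to its unique error category.

    ``school_rule`` selects the predicate of the rare few-fish-scored-as-school
    class: ``"label"`` uses the mirror-symmetric N < low AND M > school form,
    ``"prose"`` the alternative N < school AND M > low form.
    """
    n, m = pair.N, pair.M
    if school_rule not in ("label", "prose"):
        raise ValidationError(f"school_rule must be 'label' or 'prose', got {school_rule!r}")
    if n == 0 and m == 0:
        return ErrorCategory.CORRECT0
    if n == 0:
        return ErrorCategory.IMG0_CLASSN
    if n > school_threshold and m < low_threshold:
        return ErrorCategory.IMG_GT20_CLASS_LT10
    if school_rule == "label":
        if n < low_threshold and m > school_threshold:
            return ErrorCategory.IMG_LT10_CLASS_GT20
    else:
        if n < school_threshold and m > low_threshold:
            return ErrorCategory.IMG_LT10_CLASS_GT20
    if m == 0:
        return ErrorCategory.IMGN_CLASS0
    if n == m:
        return ErrorCategory.CORRECTN
    return ErrorCategory.IMGN_CLASSM


def _mean(values: Sequence[float]) -> float:
    return float(sum(values)) / len(values) if values else math.nan


@dataclass(frozen=True)
class EvaluationSummary:
    """Tallies, percentages and conditional statistics over an evaluation set."""

    total: int
    counts: Mapping[ErrorCategory, int]
    percentages: Mapping[ErrorCategory, float]
    n_with_fish_manual: int
    n_with_fish_auto: int
    pct_with_fish_manual: float
    pct_with_fish_auto: float
    pct_correct0_of_fishless: float
    pct_correctN_of_fishy: float
    pct_error_free: float
    pct_small_error_classes: float
    mean_M_given_Img0_ClassN: float
    mean_N_given_ImgN_Class0: float
    mean_abs_diff_ImgN_ClassM_MgtN: float
    mean_abs_diff_ImgN_ClassM_MltN: float
    mean_M_ImgN_ClassM_MgtN: float
    mean_N_ImgN_ClassM_MltN: float
    n_MgtN: int


def summarize(
    pairs: Sequence[CountPair],
    school_threshold: int = SCHOOL_THRESHOLD,
    low_threshold: int = LOW_THRESHOLD,
    school_rule: str = "label",
) -> EvaluationSummary:
    """Classify every pair and compute the summary-table statistics.

    Conditional percentages use their natural denominators: frames without
    fish by the manual count for ``Correct0``, frames with fish for
    ``CorrectN``.  The error-free share is (Correct0 + CorrectN) / total and
    the small-error share is the two zero-confusion classes over the total.
    Category means: mean automatic count for Img0-ClassN, mean manual count
    for ImgN-Class0, and mean absolute discrepancy |M - N| within each
    ImgN-ClassM subcase (the raw mean M and mean N are exposed as well).
    """
    if not pairs:
        raise ValidationError("cannot summarize an empty evaluation set")
    cats = [
        classify_pair(p, school_threshold, low_threshold, school_rule) for p in pairs
    ]
    tallies = Counter(cats)
    total = len(pairs)
    counts = {cat: tallies.get(cat, 0) for cat in CATEGORY_ORDER}
    percentages = {cat: 100.0 * counts[cat] / total for cat in CATEGORY_ORDER}

    n_fishless = sum(1 for p in pairs if p.N == 0)
    n_fishy = total - n_fishless
    n_auto_fish = sum(1 for p in pairs if p.M > 0)

    img0_classN_M = [p.M for p, c in zip(pairs, cats) if c is ErrorCategory.IMG0_CLASSN]
    imgN_class0_N = [p.N for p, c in zip(pairs, cats) if c is ErrorCategory.IMGN_CLASS0]
    over = [p for p, c in zip(pairs, cats) if c is ErrorCategory.IMGN_CLASSM and p.M > p.N]
    under = [p for p, c in zip(pairs, cats) if c is ErrorCategory.IMGN_CLASSM and p.M < p.N]

    def pct(num: int, den: int) -> float:
        return 100.0 * num / den if den else math.nan

    return EvaluationSummary(
        total=total,
        counts=counts,
        percentages=percentages,
        n_with_fish_manual=n_fishy,
        n_with_fish_auto=n_auto_fish,
        pct_with_fish_manual=pct(n_fishy, total),
        pct_with_fish_auto=pct(n_auto_fish, total),
        pct_correct0_of_fishless=pct(counts[ErrorCategory.CORRECT0], n_fishless),
        pct_correctN_of_fishy=pct(counts[ErrorCategory.CORRECTN], n_fishy),
        pct_error_free=pct(
            counts[ErrorCategory.CORRECT0] + counts[ErrorCategory.CORRECTN], total
        ),
        pct_small_error_classes=pct(
            counts[ErrorCategory.IMG0_CLASSN] + counts[ErrorCategory.IMGN_CLASS0], total
        ),
        mean_M_given_Img0_ClassN=_mean(img0_classN_M),
        mean_N_given_ImgN_Class0=_mean(imgN_class0_N),
        mean_abs_diff_ImgN_ClassM_MgtN=_mean([p.M - p.N for p in over]),
        mean_abs_diff_ImgN_ClassM_MltN=_mean([p.N - p.M for p in under]),
        mean_M_ImgN_ClassM_MgtN=_mean([p.M for p in over]),
        mean_N_ImgN_ClassM_MltN=_mean([p.N for p in under]),
        n_MgtN=len(over),
    )


_MEAN_FIELDS = {
    ErrorCategory.IMG0_CLASSN: "mean_M_given_Img0_ClassN",
    ErrorCategory.IMGN_CLASS0: "mean_N_given_ImgN_Class0",
}


def format_table2(summary: EvaluationSummary) -> str:
    """Render the summary as a deterministic CSV table.

    Columns: category, count, percent (1 decimal), mean (1 decimal where the
    category has one; the miscount class shows both subcase means).  Footer
    rows carry the conditional statistics.
    """
    lines = ["category,count,percent,mean"]
    for cat in CATEGORY_ORDER:
        mean_txt = ""
        if cat in _MEAN_FIELDS:
            v = getattr(summary, _MEAN_FIELDS[cat])
            mean_txt = "" if math.isnan(v) else f"{v:.1f}"
        elif cat is ErrorCategory.IMGN_CLASSM:
            gt, lt = (
                summary.mean_abs_diff_ImgN_ClassM_MgtN,
                summary.mean_abs_diff_ImgN_ClassM_MltN,
            )
            parts = []
            if not math.isnan(gt):
                parts.append(f"M>N: {gt:.1f}")
            if not math.isnan(lt):
                parts.append(f"M<N: {lt:.1f}")
            mean_txt = "; ".join(parts)
        lines.append(
            f"{cat.value},{summary.counts[cat]},{summary.percentages[cat]:.1f},\"{mean_txt}\""
        )
    lines += [
        f"with_fish_manual,{summary.n_with_fish_manual},{summary.pct_with_fish_manual:.1f},\"\"",
        f"with_fish_auto,{summary.n_with_fish_auto},{summary.pct_with_fish_auto:.1f},\"\"",
        f"error_free,,{summary.pct_error_free:.1f},\"\"",
        f"small_error_classes,,{summary.pct_small_error_classes:.1f},\"\"",
    ]
    return "\n".join(lines) + "\n"


def parse_table2(text: str) -> dict[str, tuple[float, float]]:
    """Parse a table produced by :func:`format_table2`.

    Returns ``{row_label: (count, percent)}`` with ``nan`` for blank counts.
    """
    rows: dict[str, tuple[float, float]] = {}
    lines = [ln for ln in text.strip().splitlines() if ln]
    for line in lines[1:]:
        name, count, percent, _ = line.split(",", 3)
        rows[name] = (float(count) if count else math.nan, float(percent))
    return rows
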