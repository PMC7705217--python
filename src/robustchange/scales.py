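"""Questionnaire definitions, sum scoring, and internal-consistency coefficients.

Instruments are described by :class:`ScaleDefinition` (item count, response
range, optional subscales, optional reverse-keyed items).  Scoring produces
plain integer sum scores; reliability is quantified by Cronbach's alpha and,
for dichotomous instruments, the Kuder-Richardson formula 20 (KR-20), which
is alpha's special case for 0/1 items.

All variance computations use the sample convention (denominator ``n - 1``),
the standard choice in psychometrics; KR-20 applies the matching ``n/(n-1)``
correction to the ``p*q`` item variances so that it agrees with alpha exactly
on the same binary matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScaleDefinition",
    "ReliabilityResult",
    "ScaleError",
    "DegenerateDataError",
    "score_scale",
    "cronbach_alpha",
    "kr20",
    "default_registry",
]


class ScaleError(ValueError):
    """Invalid scale definition or item responses."""


class DegenerateDataError(ScaleError):
    """Data admit no meaningful reliability coefficient (zero total variance)."""


@dataclass(frozen=True)
class ScaleDefinition:
    """Metadata for one self-report instrument.

    Parameters
    ----------
    name : str
        Short identifier, e.g. ``"pswq"``.
    n_items : int
        Number of items.
    item_min, item_max : int
        Lowest and highest response option; every response must fall inside
        ``[item_min, item_max]``.
    dichotomous : bool
        True for yes/no instruments; implies a 0/1 response range.
    subscales : dict[str, tuple[int, ...]]
        Optional named item subsets, 1-based indices into the item list.
    reverse_items : tuple[int, ...]
        1-based indices of reverse-keyed items; scoring maps response ``x``
        to ``item_min + item_max - x`` for these.  Default scale definitions
        apply no reversal.
    reference_window : str
        Free-text recall window, e.g. ``"last 4 weeks"``.
    """

    name: str
    n_items: int
    item_min: int
    item_max: int
    dichotomous: bool = False
    subscales: dict[str, tuple[int, ...]] = field(default_factory=dict)
    reverse_items: tuple[int, ...] = ()
    reference_window: str = ""

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ScaleError(f"{self.name}: n_items must be positive")
        if self.item_min >= self.item_max:
            raise ScaleError(f"{self.name}: item_min must be < item_max")
        if self.dichotomous and (self.item_min, self.item_max) != (0, 1):
            raise ScaleError(f"{self.name}: dichotomous scales must use a 0/1 range")
        for sub, items in self.subscales.items():
            if len(items) == 0:
                raise ScaleError(f"{self.name}/{sub}: empty subscale")
            for idx in items:
                if not 1 <= idx <= self.n_items:
                    raise ScaleError(
                        f"{self.name}/{sub}: item index {idx} outside [1, {self.n_items}]"
                    )
        for idx in self.reverse_items:
            if not 1 <= idx <= self.n_items:
                raise ScaleError(f"{self.name}: reverse item {idx} outside [1, {self.n_items}]")

    def score_range(self, subset: str | None = None) -> tuple[int, int]:
        """Implied (min, max) sum score for the full scale or a named subscale."""
        k = self.n_items if subset is None else len(self.subscales[subset])
        return k * self.item_min, k * self.item_max


@dataclass(frozen=True)
class ReliabilityResult:
    """An internal-consistency coefficient for one scale at one time point."""

    scale_name: str
    coefficient_type: str  # "alpha" or "kr20"
    value: float
    n_respondents: int
    timepoint: str = "T0"

    def __post_init__(self) -> None:
        if self.coefficient_type not in ("alpha", "kr20"):
            raise ScaleError(f"unknown coefficient type {self.coefficient_type!r}")
        if np.isfinite(self.value) and self.value > 1.0 + 1e-12:
            raise ScaleError("reliability coefficient cannot exceed 1")


def _as_item_matrix(item_matrix) -> np.ndarray:
    arr = np.asarray(item_matrix, dtype=float)
    if arr.ndim != 2:
        raise ScaleError("item matrix must be 2-D (respondents x items)")
    bad = np.argwhere(~np.isfinite(arr))
    if bad.size:
        r, c = bad[0]
        raise ScaleError(f"missing/non-finite response at respondent {r}, item {c + 1}")
    return arr


def score_scale(item_matrix, scale: ScaleDefinition, subset: str | None = None) -> np.ndarray:
    """Sum-score a respondents-by-items matrix for a scale or named subscale.

    The matrix must have one column per item of the full scale (columns are
    selected internally when ``subset`` is given) or, alternatively, exactly
    the subset's columns.  Responses outside the declared range and missing
    entries are rejected with coordinates; no imputation or proration is done.
    """
    arr = _as_item_matrix(item_matrix)

    if subset is not None:
        if subset not in scale.subscales:
            raise ScaleError(f"{scale.name}: unknown subscale {subset!r}")
        idx = np.asarray(scale.subscales[subset], dtype=int) - 1
        if arr.shape[1] == scale.n_items:
            cols = idx
        elif arr.shape[1] == len(idx):
            cols = np.arange(len(idx))
            idx_full = np.asarray(scale.subscales[subset], dtype=int)
        else:
            raise ScaleError(
                f"{scale.name}/{subset}: expected {scale.n_items} or {len(idx)} columns, "
                f"got {arr.shape[1]}"
            )
        sub = arr[:, cols]
        item_numbers = (idx + 1) if arr.shape[1] == scale.n_items else idx_full
    else:
        if arr.shape[1] != scale.n_items:
            raise ScaleError(
                f"{scale.name}: expected {scale.n_items} columns, got {arr.shape[1]}"
            )
        sub = arr
        item_numbers = np.arange(1, scale.n_items + 1)

    out_of_range = (sub < scale.item_min) | (sub > scale.item_max)
    if out_of_range.any():
        r, c = np.argwhere(out_of_range)[0]
        raise ScaleError(
            f"{scale.name}: response {sub[r, c]:g} outside "
            f"[{scale.item_min}, {scale.item_max}] at respondent {r}, item {item_numbers[c]}"
        )

    reversed_set = set(scale.reverse_items)
    if reversed_set:
        flip = np.array([n in reversed_set for n in item_numbers])
        sub = sub.copy()
        sub[:, flip] = scale.item_min + scale.item_max - sub[:, flip]

    return sub.sum(axis=1)


def cronbach_alpha(
    item_matrix,
    scale_name: str = "",
    timepoint: str = "T0",
) -> ReliabilityResult:
    """Cronbach's alpha: ``k/(k-1) * (1 - sum(var_item) / var_total)``.

    Item and total-score variances use the ``n - 1`` denominator.  Requires at
    least two items, three respondents, and non-zero total-score variance.
    """
    arr = _as_item_matrix(item_matrix)
    n, k = arr.shape
    if k < 2:
        raise ScaleError("alpha requires at least 2 items")
    if n < 3:
        raise ScaleError("alpha requires at least 3 respondents")

    item_vars = arr.var(axis=0, ddof=1)
    total_var = arr.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise DegenerateDataError("total-score variance is zero; alpha is undefined")

    value = k / (k - 1) * (1.0 - item_vars.sum() / total_var)
    return ReliabilityResult(scale_name, "alpha", float(value), n, timepoint)


def kr20(binary_matrix, scale_name: str = "", timepoint: str = "T0") -> ReliabilityResult:
    """Kuder-Richardson 20 for dichotomous (0/1) items.

    Computed from the item proportions ``p_i`` as
    ``k/(k-1) * (1 - sum(p_i * q_i * n/(n-1)) / var_total)``; the ``n/(n-1)``
    factor matches the sample-variance convention used by
    :func:`cronbach_alpha`, so the two coincide exactly on binary data.
    """
    arr = _as_item_matrix(binary_matrix)
    if not np.isin(arr, (0.0, 1.0)).all():
        bad = np.argwhere(~np.isin(arr, (0.0, 1.0)))[0]
        raise ScaleError(f"non-binary entry at respondent {bad[0]}, item {bad[1] + 1}")
    n, k = arr.shape
    if k < 2:
        raise ScaleError("KR-20 requires at least 2 items")
    if n < 3:
        raise ScaleError("KR-20 requires at least 3 respondents")

    p = arr.mean(axis=0)
    pq = p * (1.0 - p) * n / (n - 1)
    total_var = arr.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise DegenerateDataError("total-score variance is zero; KR-20 is undefined")

    value = k / (k - 1) * (1.0 - pq.sum() / total_var)
    return ReliabilityResult(scale_name, "kr20", float(value), n, timepoint)


def default_registry() -> dict[str, ScaleDefinition]:
    """The instrument set of the pre/post symptom-change survey.

    Subscale item indices are positional within each instrument's item list
    (item wordings are out of scope); reverse keying is disabled throughout.
    """
    return {
        s.name: s
        for s in (
            ScaleDefinition("fks", 18, 0, 4, reference_window="last week"),
            ScaleDefinition("cahsa", 9, 0, 10, reference_window="last 4 weeks"),
            ScaleDefinition("dass_d", 7, 0, 3, reference_window="past week"),
            ScaleDefinition(
                "ede_q",
                22,
                0,
                6,
                subscales={
                    "restraint": tuple(range(1, 6)),
                    "eating_concern": tuple(range(6, 11)),
                    "weight_concern": tuple(range(11, 16)),
                    "shape_concern": tuple(range(15, 23)),
                },
                reference_window="past 28 days",
            ),
            ScaleDefinition(
                "phq_panic",
                15,
                0,
                1,
                dichotomous=True,
                # items 5-15 list physical symptoms of a panic attack; their
                # sum is the severity score
                subscales={"severity": tuple(range(5, 16))},
                reference_window="last 4 weeks",
            ),
            ScaleDefinition("phq_stress", 10, 0, 2, reference_window="last 4 weeks"),
            ScaleDefinition("pswq", 16, 1, 5),
            ScaleDefinition("sias", 20, 0, 4),
            ScaleDefinition("sps", 20, 0, 4),
            ScaleDefinition("wi", 14, 0, 1, dichotomous=True),
            ScaleDefinition(
                "ybocs",
                10,
                0,
                4,
                subscales={
                    "obsessions": tuple(range(1, 6)),
                    "compulsions": tuple(range(6, 11)),
                },
                reference_window="last 7 days",
            ),
        )
    }
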