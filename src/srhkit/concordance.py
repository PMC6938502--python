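"""Diagnostic-concordance statistics for multi-rater survey data.

Raters (neuropathologists) answer a fixed set of questions about each case
under each imaging modality (SRH, H&E frozen section, H&E FFPE).  Their
answers are compared with reference labels to produce, per Table-1 cell
class:

* **percent agreement** — share of cases matching the reference;
* **Cohen's kappa** — chance-corrected agreement of one rater against the
  reference, with chance from the product of marginal label frequencies;
* **Fleiss' kappa** — chance-corrected agreement *among* the raters;
* **relative accuracy** — SRH percent agreement as a fraction of the H&E
  FFPE percent agreement for the same rater and question, computed on
  integer agreeing-case counts (see :func:`relative_accuracy`);
* **mean confidence** — average of the 1-4 self-reported confidence scores.

Differential-diagnosis answers are lists; by default a differential counts
as agreeing when the reference diagnosis appears anywhere in the list.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

MODALITIES = ("SRH", "HE_frozen", "HE_FFPE")
QUESTIONS = (
    "neoplasm_description",
    "architectural_pattern",
    "nuclear_shape",
    "differential",
    "final_diagnosis",
)
CONFIDENCE_QUESTION = "confidence"
CONFIDENCE_LEVELS = (1, 2, 3, 4)

#: Separator between entries of a differential-diagnosis list.
DIFFERENTIAL_SEP = ";"

#: Answer vocabulary per question, used when synthesizing survey tables.
QUESTION_CATEGORIES = {
    "neoplasm_description": ["epithelioid", "spindle cell", "myxoid", "chondroid", "other"],
    "architectural_pattern": ["lobular", "fascicular", "glandular", "nested",
                              "papillary", "sheeting", "other"],
    "nuclear_shape": ["rounded", "elongated", "other"],
    "differential": ["meningioma", "schwannoma", "chordoma", "chondrosarcoma",
                     "pituitary adenoma", "craniopharyngioma"],
    "final_diagnosis": ["meningioma", "schwannoma", "chordoma", "chondrosarcoma",
                        "pituitary adenoma", "craniopharyngioma"],
}


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (for non-negative x)."""
    return int(math.floor(x + 0.5))


def _norm(label) -> str:
    return str(label).strip().casefold()


def response_matches(response, reference, question: str = "",
                     differential_scoring: str = "membership") -> bool:
    """Does a single response agree with the reference label?

    Differential answers are ``;``-separated lists; under "membership"
    scoring they agree when the reference appears anywhere in the list,
    under "exact" only when the list is exactly the reference.
    """
    if question == "differential" and differential_scoring == "membership":
        options = {_norm(p) for p in str(response).split(DIFFERENTIAL_SEP)}
        return _norm(reference) in options
    return _norm(response) == _norm(reference)


class PercentAgreement(NamedTuple):
    matches: int
    n: int

    @property
    def percent(self) -> float:
        return 100.0 * self.matches / self.n

    @property
    def percent_rounded(self) -> int:
        return round_half_up(self.percent)


def percent_agreement(responses: Sequence, reference: Sequence) -> PercentAgreement:
    """Share of cases where the response equals the reference label.

    Returns both the exact fraction (``.percent``) and the nearest-integer
    percent (``.percent_rounded``), the granularity at which such surveys
    are reported.
    """
    if len(responses) != len(reference):
        raise ValueError("responses and reference must cover the same cases")
    n = len(responses)
    if n == 0:
        raise ValueError("cannot compute agreement over zero cases")
    matches = sum(_norm(a) == _norm(b) for a, b in zip(responses, reference))
    return PercentAgreement(matches, n)


def cohens_kappa(responses: Sequence, reference: Sequence) -> float:
    """Cohen's kappa between one rater and the reference.

    kappa = (p_o - p_e) / (1 - p_e), with chance agreement p_e from the
    product of the two marginal label distributions.  Perfect observed
    agreement returns exactly 1, even in the degenerate constant-label
    case.  If both sides are constant with p_o < 1 the statistic is
    undefined and NaN is returned with a warning.
    """
    if len(responses) != len(reference):
        raise ValueError("responses and reference must cover the same cases")
    if len(responses) < 2:
        raise ValueError("Cohen's kappa needs at least 2 cases")
    a = [_norm(x) for x in responses]
    b = [_norm(x) for x in reference]
    n = len(a)
    p_o = sum(x == y for x, y in zip(a, b)) / n
    if p_o == 1.0:
        return 1.0
    labels = sorted(set(a) | set(b))
    p_e = sum((a.count(c) / n) * (b.count(c) / n) for c in labels)
    if p_e >= 1.0:
        warnings.warn("Cohen's kappa undefined: chance agreement is 1", stacklevel=2)
        return float("nan")
    return (p_o - p_e) / (1.0 - p_e)


def fleiss_kappa(ratings: np.ndarray) -> float:
    """Fleiss' kappa from a (cases x categories) table of label counts.

    Every case must have been rated by the same number (>= 2) of raters.
    Returns NaN with a warning when only a single category is ever used
    (chance agreement 1, statistic undefined).
    """
    counts = np.asarray(ratings, dtype=float)
    if counts.ndim != 2:
        raise ValueError("ratings must be a 2-D (cases x categories) count table")
    n_raters = counts.sum(axis=1)
    if counts.shape[0] == 0 or n_raters[0] < 2:
        raise ValueError("Fleiss' kappa needs >= 2 raters per case")
    if not (n_raters == n_raters[0]).all():
        raise ValueError("every case must have the same number of raters")
    n = n_raters[0]
    p_i = ((counts ** 2).sum(axis=1) - n) / (n * (n - 1))
    p_bar = p_i.mean()
    p_j = counts.sum(axis=0) / counts.sum()
    p_e = (p_j ** 2).sum()
    if p_e >= 1.0:
        warnings.warn("Fleiss' kappa undefined: a single category was always used",
                      stacklevel=2)
        return float("nan")
    return float((p_bar - p_e) / (1.0 - p_e))


@dataclass
class RelativeAccuracy:
    percent: int | None    # rounded ratio of agreeing-case counts, %
    ratio: float           # unrounded count ratio, %
    srh_count: int
    ffpe_count: int


def relative_accuracy(srh_pa: float, ffpe_pa: float, n_cases: int) -> RelativeAccuracy:
    """SRH accuracy relative to the H&E FFPE gold standard.

    Both percent agreements are first converted back to integer
    agreeing-case counts out of ``n_cases`` (nearest integer); the counts
    are divided and the result expressed as a nearest-integer percent.
    Working on counts rather than on the rounded percentages matters: with
    16 cases, 75% vs 81% is 12/13 agreeing cases = 92%, where the rounded
    percentage ratio would print 93%.  The unrounded count ratio is also
    returned.

    A zero FFPE agreement leaves the ratio undefined (``percent`` is None).
    """
    if n_cases <= 0:
        raise ValueError("n_cases must be positive")
    if not (0 <= srh_pa <= 100 and 0 <= ffpe_pa <= 100):
        raise ValueError("percent agreements must be in [0, 100]")
    srh_count = round_half_up(srh_pa * n_cases / 100.0)
    ffpe_count = round_half_up(ffpe_pa * n_cases / 100.0)
    if ffpe_count == 0:
        return RelativeAccuracy(None, float("nan"), srh_count, ffpe_count)
    ratio = 100.0 * srh_count / ffpe_count
    return RelativeAccuracy(round_half_up(ratio), ratio, srh_count, ffpe_count)


# ---------------------------------------------------------------------------
# Survey table and report


@dataclass
class SurveyTable:
    """Long-format survey responses plus per-question reference labels.

    ``responses`` columns: case_id, rater_id, modality, question, response.
    ``reference`` columns: case_id, question, response.
    """

    responses: pd.DataFrame
    reference: pd.DataFrame

    def __post_init__(self):
        need = {"case_id", "rater_id", "modality", "question", "response"}
        if not need.issubset(self.responses.columns):
            raise ValueError(f"responses must have columns {sorted(need)}")
        need_ref = {"case_id", "question", "response"}
        if not need_ref.issubset(self.reference.columns):
            raise ValueError(f"reference must have columns {sorted(need_ref)}")
        if len(self.responses) == 0:
            raise ValueError("survey table is empty")
        key = ["case_id", "rater_id", "modality", "question"]
        if self.responses.duplicated(key).any():
            dupes = self.responses[self.responses.duplicated(key, keep=False)]
            raise ValueError(f"multiple responses for the same key:\n{dupes[key]}")
        bad_mod = set(self.responses.modality) - set(MODALITIES)
        if bad_mod:
            raise ValueError(f"unknown modalities {sorted(bad_mod)}; expected {MODALITIES}")
        conf = self.responses[self.responses.question == CONFIDENCE_QUESTION]
        if len(conf):
            vals = pd.to_numeric(conf.response, errors="coerce")
            if vals.isna().any() or not vals.isin(CONFIDENCE_LEVELS).all():
                raise ValueError("confidence responses must be integers in {1, 2, 3, 4}")

    @property
    def raters(self) -> list:
        return sorted(self.responses.rater_id.unique())

    @property
    def case_ids(self) -> list:
        return sorted(self.reference.case_id.unique())

    @classmethod
    def from_csv(cls, responses_path, reference_path) -> "SurveyTable":
        return cls(pd.read_csv(responses_path), pd.read_csv(reference_path))


@dataclass
class AgreementReport:
    """Per-cell agreement statistics in the layout of a modality-comparison table."""

    agreement: pd.DataFrame        # rater, modality, question, n, matches, percent, kappa
    fleiss: pd.DataFrame           # modality, question, n, kappa
    relative: pd.DataFrame         # rater, question, srh/ffpe percents+counts, percent
    confidence: pd.DataFrame       # rater, modality, n, mean_confidence
    n_cases: int

    def agreement_cell(self, rater, modality, question) -> pd.Series:
        df = self.agreement
        sel = df[(df.rater == rater) & (df.modality == modality) & (df.question == question)]
        if len(sel) != 1:
            raise KeyError((rater, modality, question))
        return sel.iloc[0]

    def relative_cell(self, rater, question) -> pd.Series:
        df = self.relative
        sel = df[(df.rater == rater) & (df.question == question)]
        if len(sel) != 1:
            raise KeyError((rater, question))
        return sel.iloc[0]

    def to_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "agreement": self.agreement.to_dict(orient="records"),
            "fleiss": self.fleiss.to_dict(orient="records"),
            "relative_accuracy": self.relative.to_dict(orient="records"),
            "confidence": self.confidence.to_dict(orient="records"),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=_json_default)

    def to_csv(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.agreement.to_csv(out / "agreement.csv", index=False)
        self.fleiss.to_csv(out / "fleiss_kappa.csv", index=False)
        self.relative.to_csv(out / "relative_accuracy.csv", index=False)
        self.confidence.to_csv(out / "confidence.csv", index=False)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return None if np.isnan(o) else float(o)
    return str(o)


def _effective_labels(merged: pd.DataFrame, question: str, scoring: str) -> tuple[list, list]:
    """Map (response, reference) pairs to comparable categorical labels.

    For list-valued differentials under membership scoring, a response that
    contains the reference is mapped onto the reference label itself so
    kappa sees it as agreement; a miss keeps the full (normalized) list as
    its own category.
    """
    resp, ref = [], []
    for r in merged.itertuples():
        ref_label = _norm(r.response_ref)
        if response_matches(r.response, r.response_ref, question, scoring):
            resp.append(ref_label)
        else:
            resp.append(_norm(r.response))
        ref.append(ref_label)
    return resp, ref


def build_report(
    table: SurveyTable,
    differential_scoring: str = "membership",
) -> AgreementReport:
    """Compute every cell class of the modality-comparison table.

    Missing responses are excluded pairwise, cell by cell, with the cell's
    effective ``n`` reported.  Cells with fewer than 2 usable cases report
    NaN kappa; Fleiss' kappa uses only cases answered by every rater.
    """
    ref = table.reference.copy()
    ref["response"] = ref.response.astype(str)
    resp = table.responses.copy()
    raters = table.raters
    n_cases = len(table.case_ids)
    if n_cases == 0:
        raise ValueError("reference contains no cases")

    agreement_rows, fleiss_rows, relative_rows, confidence_rows = [], [], [], []

    for question in QUESTIONS:
        qref = ref[ref.question == question][["case_id", "response"]]
        for modality in MODALITIES:
            per_case_labels = {}
            for rater in raters:
                cell = resp[(resp.rater_id == rater) & (resp.modality == modality)
                            & (resp.question == question)].dropna(subset=["response"])
                merged = cell.merge(qref, on="case_id", suffixes=("", "_ref"))
                n = len(merged)
                if n == 0:
                    agreement_rows.append(dict(rater=rater, modality=modality,
                                               question=question, n=0, matches=np.nan,
                                               percent=np.nan, kappa=np.nan))
                    continue
                labels, ref_labels = _effective_labels(merged, question, differential_scoring)
                matches = sum(a == b for a, b in zip(labels, ref_labels))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    kappa = cohens_kappa(labels, ref_labels) if n >= 2 else float("nan")
                agreement_rows.append(dict(
                    rater=rater, modality=modality, question=question, n=n,
                    matches=matches, percent=100.0 * matches / n, kappa=kappa,
                ))
                for cid, lab in zip(merged.case_id, labels):
                    per_case_labels.setdefault(cid, {})[rater] = lab
            # Fleiss over cases rated by every rater
            complete = {cid: d for cid, d in per_case_labels.items() if len(d) == len(raters)}
            if complete and len(raters) >= 2:
                cats = sorted({lab for d in complete.values() for lab in d.values()})
                counts = np.zeros((len(complete), len(cats)))
                for i, (_, d) in enumerate(sorted(complete.items(), key=lambda kv: str(kv[0]))):
                    for lab in d.values():
                        counts[i, cats.index(lab)] += 1
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    kf = fleiss_kappa(counts)
            else:
                kf = float("nan")
            fleiss_rows.append(dict(modality=modality, question=question,
                                    n=len(complete), kappa=kf))

    agreement = pd.DataFrame(agreement_rows)
    for question in QUESTIONS:
        for rater in raters:
            srh = agreement[(agreement.rater == rater) & (agreement.modality == "SRH")
                            & (agreement.question == question)]
            ffpe = agreement[(agreement.rater == rater) & (agreement.modality == "HE_FFPE")
                             & (agreement.question == question)]
            row = dict(rater=rater, question=question, srh_percent=np.nan,
                       ffpe_percent=np.nan, percent=np.nan, ratio=np.nan)
            if len(srh) and len(ffpe) and srh.iloc[0].n > 0 and ffpe.iloc[0].n > 0:
                ra = relative_accuracy(srh.iloc[0].percent, ffpe.iloc[0].percent, n_cases)
                row.update(srh_percent=srh.iloc[0].percent, ffpe_percent=ffpe.iloc[0].percent,
                           percent=np.nan if ra.percent is None else ra.percent,
                           ratio=ra.ratio)
            relative_rows.append(row)

    conf = resp[resp.question == CONFIDENCE_QUESTION].copy()
    if len(conf):
        conf["value"] = pd.to_numeric(conf.response)
        for (rater, modality), grp in conf.groupby(["rater_id", "modality"]):
            confidence_rows.append(dict(rater=rater, modality=modality, n=len(grp),
                                        mean_confidence=grp.value.mean()))

    return AgreementReport(
        agreement=agreement,
        fleiss=pd.DataFrame(fleiss_rows),
        relative=pd.DataFrame(relative_rows),
        confidence=pd.DataFrame(confidence_rows,
                                columns=["rater", "modality", "n", "mean_confidence"]),
        n_cases=n_cases,
    )


# ---------------------------------------------------------------------------
# Synthetic survey construction


def synthetic_survey_table(
    match_counts: dict,
    n_cases: int,
    seed: int = 0,
    confidence_means: dict | None = None,
) -> SurveyTable:
    """Build a survey table realizing prescribed agreement counts.

    ``match_counts`` maps ``(rater, modality, question)`` to the number of
    cases (out of ``n_cases``) on which that rater's answer must agree with
    the reference.  Reference labels and disagreeing answers are drawn from
    the question's answer vocabulary (deterministically, given ``seed``).
    Differential answers are two-entry lists; an agreeing differential
    contains the reference diagnosis, a disagreeing one does not.

    ``confidence_means`` optionally maps ``(rater, modality)`` to a target
    mean confidence in [1, 4]; scores are assigned per case so the mean is
    as close to the target as a 1-4 integer scale allows.
    """
    rng = np.random.default_rng(seed)
    case_ids = [f"case{i:02d}" for i in range(1, n_cases + 1)]
    questions = sorted({q for (_, _, q) in match_counts})
    ref_rows = []
    reference = {}
    for q in questions:
        cats = QUESTION_CATEGORIES[q]
        for cid in case_ids:
            lab = cats[rng.integers(len(cats))]
            reference[(cid, q)] = lab
            ref_rows.append(dict(case_id=cid, question=q, response=lab))

    rows = []
    for (rater, modality, question), k in sorted(match_counts.items(), key=str):
        if not (0 <= k <= n_cases):
            raise ValueError(f"match count {k} out of range for n_cases={n_cases}")
        cats = QUESTION_CATEGORIES[question]
        agree_cases = set(rng.choice(n_cases, size=k, replace=False).tolist())
        for i, cid in enumerate(case_ids):
            ref_lab = reference[(cid, question)]
            if i in agree_cases:
                if question == "differential":
                    other = next(c for c in cats if c != ref_lab)
                    resp = f"{ref_lab}{DIFFERENTIAL_SEP} {other}"
                else:
                    resp = ref_lab
            else:
                wrong = [c for c in cats if c != ref_lab]
                pick = wrong[rng.integers(len(wrong))]
                if question == "differential":
                    second = [c for c in wrong if c != pick]
                    resp = f"{pick}{DIFFERENTIAL_SEP} {second[rng.integers(len(second))]}" \
                        if second else pick
                else:
                    resp = pick
            rows.append(dict(case_id=cid, rater_id=rater, modality=modality,
                             question=question, response=resp))

    if confidence_means:
        for (rater, modality), target in sorted(confidence_means.items(), key=str):
            total = round_half_up(target * n_cases)
            base, extra = divmod(total, n_cases)
            base = min(max(base, 1), 4)
            for i, cid in enumerate(case_ids):
                score = min(base + (1 if i < extra else 0), 4)
                rows.append(dict(case_id=cid, rater_id=rater, modality=modality,
                                 question=CONFIDENCE_QUESTION, response=score))

    return SurveyTable(pd.DataFrame(rows), pd.DataFrame(ref_rows))
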