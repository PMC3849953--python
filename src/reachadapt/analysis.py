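"""Condition coding, duration regression, and session-level summaries.

The influence of the segment conditions on the executed duration is studied
with an ordinary least-squares regression,

    duration = b0 + b1 x1 + b2 x2 + ... + bi xi,

whose predictors are 0/1 dummies. Each categorical condition contributes
dummies against a reference category: Virtual (EV0), Return (RR0), Against
Gravity (G0) and a Large cross-body component (CB0) are the references, so
the active dummies are Embedded (EV1), Reach (RR1), Towards Gravity (G1),
Ground Level (G2) and Small (CB1). Participants enter as dummies against a
reference participant. The model with interaction terms additionally
includes the seven products EV1G1, EV1G2, RR1G1, RR1G2, RR1CB1, G1CB1 and
G2CB1.

Fitting follows the statsmodels shape: build a
:class:`SegmentDurationModel` from tidy records, call :meth:`fit`, and read
estimates, diagnostics and tables off the returned
:class:`SegmentDurationResults`. Prediction by coefficient substitution
(:func:`predict_duration`) also accepts a plain mapping of coefficients, so
published coefficient tables can be substituted without refitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.stattools import durbin_watson

from .metrics import count_converged_segments
from .trajectory import Segment

__all__ = [
    "TERM_CONSTANT",
    "MAIN_TERMS",
    "INTERACTION_TERMS",
    "ConditionCoding",
    "encode",
    "participant_term",
    "SegmentDurationModel",
    "SegmentDurationResults",
    "ChangeStatistics",
    "change_statistics",
    "change_statistics_from_r2",
    "predict_duration",
    "condition_duration_table",
    "records_from_logs",
    "iteration_level_summary",
    "segment_level_summary",
    "plot_iteration_level",
    "plot_segment_level",
]

TERM_CONSTANT = "Constant"
TERM_EMBEDDED = "Embedded"
TERM_REACH = "Reach"
TERM_TOWARDS = "Towards Gravity"
TERM_GROUND = "Ground Level"
TERM_SMALL = "Small"

MAIN_TERMS = (TERM_EMBEDDED, TERM_REACH, TERM_TOWARDS, TERM_GROUND, TERM_SMALL)
#: interaction dummies: products of the main-effect dummies named by symbol
INTERACTION_TERMS = ("EV1G1", "EV1G2", "RR1G1", "RR1G2", "RR1CB1", "G1CB1", "G2CB1")


def participant_term(participant_id: int) -> str:
    return f"Participant {participant_id}"


@dataclass(frozen=True)
class ConditionCoding:
    """Dummy coding of one segment execution.

    ``participant`` is the dummy column name of the executing participant,
    or ``None`` for the reference participant.
    """

    ev1: int = 0
    rr1: int = 0
    g1: int = 0
    g2: int = 0
    cb1: int = 0
    participant: str | None = None
    include_interactions: bool = True

    def __post_init__(self) -> None:
        for name in ("ev1", "rr1", "g1", "g2", "cb1"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1")
        if self.g1 and self.g2:
            raise ValueError("G1 and G2 are mutually exclusive gravity dummies")

    @property
    def interactions(self) -> dict[str, int]:
        return {
            "EV1G1": self.ev1 * self.g1,
            "EV1G2": self.ev1 * self.g2,
            "RR1G1": self.rr1 * self.g1,
            "RR1G2": self.rr1 * self.g2,
            "RR1CB1": self.rr1 * self.cb1,
            "G1CB1": self.g1 * self.cb1,
            "G2CB1": self.g2 * self.cb1,
        }

    def as_dict(self) -> dict[str, int]:
        """Map predictor term names to dummy values (zero entries included)."""
        out = {
            TERM_EMBEDDED: self.ev1,
            TERM_REACH: self.rr1,
            TERM_TOWARDS: self.g1,
            TERM_GROUND: self.g2,
            TERM_SMALL: self.cb1,
        }
        if self.include_interactions:
            out.update(self.interactions)
        if self.participant is not None:
            out[self.participant] = 1
        return out

    def decode(self) -> dict[str, str]:
        """Recover the condition labels from the dummy values."""
        return {
            "embedded_virtual": "Embedded" if self.ev1 else "Virtual",
            "reach_return": "Reach" if self.rr1 else "Return",
            "gravity": "Towards Gravity" if self.g1 else ("Ground Level" if self.g2 else "Against Gravity"),
            "cross_body": "Small" if self.cb1 else "Large",
        }


def encode(
    segment: Segment,
    participant_id: int | None = None,
    reference_participant: int = 1,
    include_interactions: bool = True,
) -> ConditionCoding:
    """Dummy-code a segment's condition labels (plus a participant dummy)."""
    participant = None
    if participant_id is not None and participant_id != reference_participant:
        participant = participant_term(participant_id)
    return ConditionCoding(
        ev1=int(segment.embedded),
        rr1=int(segment.reach),
        g1=int(segment.gravity == "towards"),
        g2=int(segment.gravity == "ground"),
        cb1=int(segment.cross_body == "small"),
        participant=participant,
        include_interactions=include_interactions,
    )


_LABEL_COLUMNS = ("embedded", "reach", "gravity", "cross_body")


def _design_from_records(
    records: pd.DataFrame,
    include_interactions: bool,
    include_participants: bool,
    reference_participant: int,
) -> tuple[pd.Series, pd.DataFrame]:
    for col in ("duration_s",) + _LABEL_COLUMNS:
        if col not in records.columns:
            raise ValueError(f"records are missing the {col!r} column")
    y = records["duration_s"].astype(float)
    X = pd.DataFrame(index=records.index)
    X[TERM_CONSTANT] = 1.0
    ev1 = records["embedded"].astype(int)
    rr1 = records["reach"].astype(int)
    g1 = (records["gravity"] == "towards").astype(int)
    g2 = (records["gravity"] == "ground").astype(int)
    cb1 = (records["cross_body"] == "small").astype(int)
    X[TERM_EMBEDDED], X[TERM_REACH] = ev1, rr1
    X[TERM_TOWARDS], X[TERM_GROUND], X[TERM_SMALL] = g1, g2, cb1
    if include_participants and "participant" in records.columns:
        for pid in sorted(records["participant"].unique()):
            if pid == reference_participant:
                continue
            X[participant_term(int(pid))] = (records["participant"] == pid).astype(int)
    if include_interactions:
        X["EV1G1"], X["EV1G2"] = ev1 * g1, ev1 * g2
        X["RR1G1"], X["RR1G2"] = rr1 * g1, rr1 * g2
        X["RR1CB1"], X["G1CB1"], X["G2CB1"] = rr1 * cb1, g1 * cb1, g2 * cb1
    return y, X.astype(float)


class SegmentDurationModel:
    """OLS model of executed duration on condition (and participant) dummies."""

    def __init__(self, endog: pd.Series, exog: pd.DataFrame):
        if TERM_CONSTANT not in exog.columns:
            raise ValueError(f"design matrix must carry a {TERM_CONSTANT!r} column")
        predictors = [c for c in exog.columns if c != TERM_CONSTANT]
        degenerate = [c for c in predictors if exog[c].nunique() < 2]
        if degenerate:
            raise ValueError(f"predictors without variation: {degenerate}")
        rank = np.linalg.matrix_rank(exog.to_numpy())
        if rank < exog.shape[1]:
            # report the offending columns: those whose removal restores full rank
            offending = [
                c
                for c in predictors
                if np.linalg.matrix_rank(exog.drop(columns=[c]).to_numpy()) == rank
            ]
            raise ValueError(f"design matrix is rank deficient; offending columns: {offending}")
        self.endog = endog.astype(float)
        self.exog = exog.astype(float)

    @classmethod
    def from_records(
        cls,
        records: pd.DataFrame,
        include_interactions: bool = True,
        include_participants: bool = True,
        reference_participant: int = 1,
    ) -> "SegmentDurationModel":
        """Build the model from tidy records.

        ``records`` needs columns ``duration_s, embedded, reach, gravity,
        cross_body`` (labels as used by :class:`~reachadapt.trajectory.Segment`)
        and optionally ``participant``.
        """
        y, X = _design_from_records(
            records, include_interactions, include_participants, reference_participant
        )
        return cls(y, X)

    def fit(self) -> "SegmentDurationResults":
        res = sm.OLS(self.endog, self.exog).fit()
        return SegmentDurationResults(self, res)


class ChangeStatistics(NamedTuple):
    r2_change: float
    f_change: float
    df1: int
    df2: int
    p_value: float


def change_statistics_from_r2(
    r2_restricted: float, r2_full: float, df1: int, df2: int
) -> ChangeStatistics:
    """Nested-model F statistic from the two R-squared values.

    F = ((R2_full - R2_restricted) / df1) / ((1 - R2_full) / df2) with df1
    added predictors and df2 residual degrees of freedom of the full model.
    """
    if df1 < 0 or df2 <= 0:
        raise ValueError("need df1 >= 0 and df2 > 0")
    r2_change = r2_full - r2_restricted
    if df1 == 0 or r2_change == 0:
        return ChangeStatistics(r2_change, 0.0, df1, df2, 1.0)
    f = (r2_change / df1) / ((1.0 - r2_full) / df2)
    p = float(scipy.stats.f.sf(f, df1, df2))
    return ChangeStatistics(float(r2_change), float(f), df1, df2, p)


class SegmentDurationResults:
    """Fitted coefficients, uncertainties and diagnostics.

    Thin results object over the statsmodels OLS fit, exposing the
    quantities reported for this kind of analysis: unstandardized
    coefficients with standard errors, standardized betas, t and p values,
    R-squared / adjusted R-squared, and the Durbin-Watson statistic of the
    residual sequence in record order.
    """

    def __init__(self, model: SegmentDurationModel, res):
        self.model = model
        self._res = res

    # -- estimates ---------------------------------------------------------
    @property
    def params(self) -> pd.Series:
        return self._res.params

    @property
    def bse(self) -> pd.Series:
        return self._res.bse

    @property
    def tvalues(self) -> pd.Series:
        return self._res.tvalues

    @property
    def pvalues(self) -> pd.Series:
        return self._res.pvalues

    @property
    def std_betas(self) -> pd.Series:
        """Standardized coefficients b_i * sd(x_i) / sd(y); NaN for the constant."""
        sd_y = float(self.model.endog.std(ddof=1))
        sd_x = self.model.exog.std(ddof=1)
        betas = self.params * sd_x / sd_y
        betas[TERM_CONSTANT] = np.nan
        return betas

    # -- fit statistics ----------------------------------------------------
    @property
    def rsquared(self) -> float:
        return float(self._res.rsquared)

    @property
    def rsquared_adj(self) -> float:
        return float(self._res.rsquared_adj)

    @property
    def nobs(self) -> int:
        return int(self._res.nobs)

    @property
    def df_resid(self) -> int:
        return int(self._res.df_resid)

    @property
    def resid(self) -> pd.Series:
        return self._res.resid

    @property
    def durbin_watson(self) -> float:
        return float(durbin_watson(self._res.resid.to_numpy()))

    def predict(self, exog: pd.DataFrame | None = None) -> np.ndarray:
        return self._res.predict(self.model.exog if exog is None else exog)

    # -- tables ------------------------------------------------------------
    def coefficients_frame(self) -> pd.DataFrame:
        """Coefficient table: B, Std. Error, Beta, t, Sig. per predictor."""
        return pd.DataFrame(
            {
                "b": self.params,
                "std_error": self.bse,
                "beta": self.std_betas,
                "t": self.tvalues,
                "sig": self.pvalues,
            }
        )

    def summary_frame(self) -> pd.DataFrame:
        """One-row model summary (R, R2, adjusted R2, SE of estimate, DW)."""
        return pd.DataFrame(
            {
                "r": [float(np.sqrt(self.rsquared))],
                "r_squared": [self.rsquared],
                "adj_r_squared": [self.rsquared_adj],
                "std_error_estimate": [float(np.sqrt(self._res.mse_resid))],
                "durbin_watson": [self.durbin_watson],
                "n": [self.nobs],
            }
        )

    def summary(self):
        """Full statsmodels summary table."""
        return self._res.summary()

    # -- derived quantities -------------------------------------------------
    def predict_duration(self, profile: "ConditionCoding | Mapping[str, float]") -> float:
        return predict_duration(self.params, profile)

    def condition_duration_table(self) -> pd.DataFrame:
        return condition_duration_table(self.params)

    def compare(self, restricted: "SegmentDurationResults") -> ChangeStatistics:
        return change_statistics(restricted, self)


def change_statistics(
    restricted: SegmentDurationResults, full: SegmentDurationResults
) -> ChangeStatistics:
    """Nested-model change statistics between two fitted models."""
    r_cols = set(restricted.model.exog.columns)
    f_cols = set(full.model.exog.columns)
    if not r_cols <= f_cols:
        raise ValueError(
            f"models are not nested; restricted has extra predictors: {sorted(r_cols - f_cols)}"
        )
    if restricted.nobs != full.nobs:
        raise ValueError("models were fitted on different numbers of observations")
    df1 = len(f_cols) - len(r_cols)
    return change_statistics_from_r2(
        restricted.rsquared, full.rsquared, df1, full.df_resid
    )


def _coefficient_map(coefficients) -> Mapping[str, float]:
    if isinstance(coefficients, SegmentDurationResults):
        return coefficients.params
    return coefficients


def predict_duration(
    coefficients: "Mapping[str, float] | SegmentDurationResults",
    profile: "ConditionCoding | Mapping[str, float]",
) -> float:
    """Substitute a condition profile into duration = b0 + sum(b_i x_i).

    ``coefficients`` maps term names (including ``Constant``) to b values —
    either a fitted result or a published coefficient table. Every non-zero
    term of the profile must have a coefficient.
    """
    coeffs = _coefficient_map(coefficients)
    if TERM_CONSTANT not in coeffs:
        raise KeyError(f"coefficients are missing the {TERM_CONSTANT!r} term")
    terms = profile.as_dict() if isinstance(profile, ConditionCoding) else dict(profile)
    value = float(coeffs[TERM_CONSTANT])
    for term, x in terms.items():
        if x == 0:
            continue
        if term not in coeffs:
            raise KeyError(f"no coefficient for profile term {term!r}")
        value += float(coeffs[term]) * x
    return value


def condition_duration_table(
    coefficients: "Mapping[str, float] | SegmentDurationResults",
) -> pd.DataFrame:
    """Predicted durations over the target-type / movement x gravity grid.

    Rows Virtual, Embedded, Return, Reach; columns Against Gravity, Towards
    Gravity, Ground Level. Each cell substitutes the corresponding dummies
    (with their interaction products) into the regression equation, all
    other conditions at their reference categories.
    """
    gravity_profiles = {
        "Against Gravity (G0)": dict(g1=0, g2=0),
        "Towards Gravity (G1)": dict(g1=1, g2=0),
        "Ground Level (G2)": dict(g1=0, g2=1),
    }
    row_profiles = {
        "Virtual (EV0)": dict(),
        "Embedded (EV1)": dict(ev1=1),
        "Return (RR0)": dict(),
        "Reach (RR1)": dict(rr1=1),
    }
    data = {
        row: [
            predict_duration(coefficients, ConditionCoding(**row_kw, **grav_kw))
            for grav_kw in gravity_profiles.values()
        ]
        for row, row_kw in row_profiles.items()
    }
    return pd.DataFrame.from_dict(
        data, orient="index", columns=list(gravity_profiles)
    )


# -- session-log summaries ---------------------------------------------------


def records_from_logs(logs, segments: Sequence[Segment]) -> pd.DataFrame:
    """Tidy AA2 duration records (with condition labels) from session logs."""
    seg_map = {s.id: s for s in segments}
    frames = []
    for log in logs:
        aa2 = log.actual_performance
        aa2 = aa2[aa2["mode"] == "AA2"].copy()
        aa2["embedded"] = aa2["seg"].map(lambda k: seg_map[k].embedded)
        aa2["reach"] = aa2["seg"].map(lambda k: seg_map[k].reach)
        aa2["gravity"] = aa2["seg"].map(lambda k: seg_map[k].gravity)
        aa2["cross_body"] = aa2["seg"].map(lambda k: seg_map[k].cross_body)
        frames.append(aa2)
    if not frames:
        return pd.DataFrame(
            columns=["participant", "seg", "duration_s", *_LABEL_COLUMNS]
        )
    return pd.concat(frames, ignore_index=True)


def iteration_level_summary(logs) -> pd.DataFrame:
    """Per participant: how many segments settled on a constant optimum."""
    rows = [
        {
            "participant": log.participant_id,
            "n_converged": count_converged_segments(log.duration_sequences.values()),
            "n_segments": len(log.duration_sequences),
        }
        for log in logs
    ]
    return pd.DataFrame(rows)


def segment_level_summary(logs) -> pd.DataFrame:
    """Per segment: how many participants settled on a constant optimum."""
    counts: dict[int, int] = {}
    totals: dict[int, int] = {}
    for log in logs:
        for seg, seq in log.duration_sequences.items():
            totals[seg] = totals.get(seg, 0) + 1
            counts[seg] = counts.get(seg, 0) + int(seq.converged)
    return pd.DataFrame(
        {
            "seg": sorted(totals),
            "n_converged": [counts[s] for s in sorted(totals)],
            "n_participants": [totals[s] for s in sorted(totals)],
        }
    )


def plot_iteration_level(summary: pd.DataFrame, ax=None):
    """Line chart of converged-segment counts per participant."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(summary["participant"], summary["n_converged"], marker="o")
    ax.set_xlabel("Participant")
    ax.set_ylabel("Segments at constant optimum")
    return ax


def plot_segment_level(summary: pd.DataFrame, ax=None):
    """Bar chart of converged-participant counts per segment."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    half = summary["n_participants"] / 2
    colors = ["tab:red" if c < h else "tab:blue" for c, h in zip(summary["n_converged"], half)]
    ax.bar(summary["seg"], summary["n_converged"], color=colors)
    ax.set_xlabel("Segment")
    ax.set_ylabel("Participants at constant optimum")
    return ax
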