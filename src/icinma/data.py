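"""Trial-level evidence: domain types, table ingest and deterministic transforms.

The evidence unit is a *contrast*: one trial-level relative effect on the
natural-log scale (a log hazard ratio for survival outcomes) with its standard
error, anchored on the trial's own reference arm.  A collection of arms and
contrasts over a treatment registry forms an :class:`EvidenceNetwork`, the
input to every downstream analysis step.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml
from scipy.stats import norm

__all__ = [
    "Treatment",
    "TrialArm",
    "ContrastObservation",
    "EvidenceNetwork",
    "RiskFlags",
    "NetworkError",
    "se_from_ci",
    "load_trial_table",
    "write_trial_table",
    "load_risk_flags",
    "merge_dose_arms",
    "resolve_auxiliary_nodes",
    "filter_low_risk",
]

log = logging.getLogger(__name__)

OUTCOMES = ("PFS", "OS")


class NetworkError(ValueError):
    """Raised when an evidence network violates a structural invariant."""


@dataclass(frozen=True)
class Treatment:
    """A treatment node. ``reportable=False`` marks auxiliary likelihood-only
    nodes (e.g. a vaccine-alone arm kept solely to anchor a trial)."""

    id: str
    label: str = ""
    reportable: bool = True


@dataclass
class TrialArm:
    trial_id: str
    treatment_id: str
    n_enrolled: int
    dose_label: str = ""
    ae_any: int | None = None
    ae_high: int | None = None

    def validate(self) -> None:
        if self.n_enrolled <= 0:
            raise NetworkError(
                f"trial {self.trial_id!r} arm {self.treatment_id!r}: "
                f"n_enrolled must be positive, got {self.n_enrolled}"
            )
        if self.ae_any is not None:
            hi = self.ae_high if self.ae_high is not None else 0
            if not (0 <= hi <= self.ae_any <= self.n_enrolled):
                raise NetworkError(
                    f"trial {self.trial_id!r} arm {self.treatment_id!r}: "
                    f"need 0 <= ae_high <= ae_any <= n, got "
                    f"({self.ae_high}, {self.ae_any}, {self.n_enrolled})"
                )


@dataclass
class ContrastObservation:
    """One observed relative effect: log effect ``y`` (comparator vs baseline)
    with standard error ``se``.  ``y < 0`` favours the comparator for
    hazard-type outcomes."""

    trial_id: str
    baseline: str
    comparator: str
    outcome: str
    y: float
    se: float
    dose_label: str = ""

    def validate(self) -> None:
        if self.se <= 0:
            raise NetworkError(
                f"trial {self.trial_id!r} contrast {self.comparator} vs "
                f"{self.baseline}: se must be positive, got {self.se}"
            )
        if self.baseline == self.comparator:
            raise NetworkError(
                f"trial {self.trial_id!r}: contrast compares {self.baseline!r} "
                "with itself"
            )
        if self.outcome not in OUTCOMES:
            raise NetworkError(
                f"trial {self.trial_id!r}: unknown outcome {self.outcome!r}"
            )


@dataclass
class EvidenceNetwork:
    """Treatments, per-trial arms and baseline-anchored contrasts."""

    treatments: dict[str, Treatment]
    arms: list[TrialArm] = field(default_factory=list)
    contrasts: list[ContrastObservation] = field(default_factory=list)

    # -- structure ---------------------------------------------------------

    @property
    def trial_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for arm in self.arms:
            seen.setdefault(arm.trial_id, None)
        return list(seen)

    def trial_roster(self) -> dict[str, list[TrialArm]]:
        roster: dict[str, list[TrialArm]] = {}
        for arm in self.arms:
            roster.setdefault(arm.trial_id, []).append(arm)
        return roster

    def contrasts_for(self, outcome: str) -> list[ContrastObservation]:
        return [c for c in self.contrasts if c.outcome == outcome]

    def graph(self, outcome: str) -> nx.Graph:
        """Comparison graph of the given outcome (nodes touched by contrasts)."""
        g = nx.Graph()
        for c in self.contrasts_for(outcome):
            g.add_edge(c.baseline, c.comparator)
        return g

    def nodes_for(self, outcome: str) -> list[str]:
        """Treatments entering the outcome's comparison graph, registry order."""
        touched = set()
        for c in self.contrasts_for(outcome):
            touched.add(c.baseline)
            touched.add(c.comparator)
        return [t for t in self.treatments if t in touched]

    def reportable_ids(self) -> list[str]:
        return [t.id for t in self.treatments.values() if t.reportable]

    # -- validation --------------------------------------------------------

    def validate(self) -> "EvidenceNetwork":
        if not self.arms:
            raise NetworkError("no trials: the evidence table is empty")
        for arm in self.arms:
            arm.validate()
            if arm.treatment_id not in self.treatments:
                raise NetworkError(
                    f"trial {arm.trial_id!r}: unknown treatment code "
                    f"{arm.treatment_id!r}"
                )
        roster = self.trial_roster()
        seen: set[tuple] = set()
        for c in self.contrasts:
            c.validate()
            for t in (c.baseline, c.comparator):
                if t not in self.treatments:
                    raise NetworkError(
                        f"trial {c.trial_id!r}: contrast uses unknown "
                        f"treatment code {t!r}"
                    )
            if c.trial_id not in roster:
                raise NetworkError(
                    f"contrast of trial {c.trial_id!r} has no arms on record"
                )
            key = (c.trial_id, c.baseline, c.comparator, c.dose_label, c.outcome)
            if key in seen:
                raise NetworkError(
                    f"duplicate contrast in trial {c.trial_id!r}: "
                    f"{c.comparator} vs {c.baseline} ({c.outcome})"
                )
            seen.add(key)
        # within one trial and outcome, all contrasts share one baseline
        base: dict[tuple, str] = {}
        for c in self.contrasts:
            k = (c.trial_id, c.outcome)
            if base.setdefault(k, c.baseline) != c.baseline:
                raise NetworkError(
                    f"trial {c.trial_id!r} mixes baselines "
                    f"{base[k]!r} and {c.baseline!r} for {c.outcome}"
                )
        return self

    def require_connected(self, outcome: str) -> None:
        g = self.graph(outcome)
        if g.number_of_nodes() == 0:
            raise NetworkError(f"no {outcome} contrasts in the network")
        if not nx.is_connected(g):
            comps = sorted(
                (sorted(comp) for comp in nx.connected_components(g)),
                key=len,
                reverse=True,
            )
            raise NetworkError(
                f"{outcome} comparison graph is disconnected; components: "
                + "; ".join("{" + ", ".join(c) + "}" for c in comps)
            )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "treatments": [
                {"id": t.id, "label": t.label, "reportable": t.reportable}
                for t in self.treatments.values()
            ],
            "arms": [
                {
                    "trial_id": a.trial_id,
                    "treatment_id": a.treatment_id,
                    "n_enrolled": a.n_enrolled,
                    "dose_label": a.dose_label,
                    "ae_any": a.ae_any,
                    "ae_high": a.ae_high,
                }
                for a in self.arms
            ],
            "contrasts": [
                {
                    "trial_id": c.trial_id,
                    "baseline": c.baseline,
                    "comparator": c.comparator,
                    "outcome": c.outcome,
                    "y": float(c.y),
                    "se": float(c.se),
                    "dose_label": c.dose_label,
                }
                for c in self.contrasts
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvidenceNetwork":
        treatments = {
            t["id"]: Treatment(t["id"], t.get("label", ""), t.get("reportable", True))
            for t in d["treatments"]
        }
        arms = [TrialArm(**a) for a in d["arms"]]
        contrasts = [ContrastObservation(**c) for c in d["contrasts"]]
        return cls(treatments, arms, contrasts).validate()

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "EvidenceNetwork":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RiskFlags:
    """Per-trial low-risk-of-bias flags for the sensitivity restriction."""

    flags: dict[str, bool]

    def require_cover(self, network: EvidenceNetwork) -> None:
        missing = [t for t in network.trial_ids if t not in self.flags]
        if missing:
            raise NetworkError(f"risk flags missing for trials: {missing}")


# ---------------------------------------------------------------------------
# deterministic transforms
# ---------------------------------------------------------------------------


def se_from_ci(lower: float, upper: float, level: float = 0.95) -> float:
    """Standard error of a log relative effect from its ratio-scale CI.

    se = (ln(upper) - ln(lower)) / (2 z), z the two-sided normal quantile of
    the stated coverage.  Scale-invariant in the bounds.
    """
    if not 0 < lower < upper:
        raise ValueError(f"need 0 < lower < upper, got ({lower}, {upper})")
    if not 0 < level < 1:
        raise ValueError(f"coverage level must be in (0, 1), got {level}")
    z = norm.ppf(0.5 * (1.0 + level))
    return (math.log(upper) - math.log(lower)) / (2.0 * z)


def _pool_iv(effects: list[tuple[float, float]]) -> tuple[float, float]:
    w = [1.0 / se**2 for _, se in effects]
    sw = sum(w)
    y = sum(wi * yi for wi, (yi, _) in zip(w, effects)) / sw
    return y, sw**-0.5


def load_trial_table(
    path: str | Path,
    schema: str = "PFS",
    treatments: dict[str, Treatment] | None = None,
) -> EvidenceNetwork:
    """Ingest the delimited per-arm evidence table.

    Expected columns: trial_id, author_year, treatment, n, hr, ci_low, ci_high,
    ae_any, ae_high, outcome, dose_label.  The reference arm carries ``ref`` in
    the hr column; empty hr cells yield arms without contrasts.  ``schema``
    labels the outcome the hr column reports.
    """
    df = pd.read_csv(path, dtype=str, comment="#", skip_blank_lines=True)
    if df.empty:
        raise NetworkError(f"no trials: {path} contains no data rows")
    df.columns = [c.strip() for c in df.columns]
    required = {"trial_id", "treatment", "n", "hr", "ci_low", "ci_high"}
    missing = required - set(df.columns)
    if missing:
        raise NetworkError(f"{path}: missing columns {sorted(missing)}")

    if treatments is None:
        from .datasets import treatment_registry

        treatments = treatment_registry()

    def cell(row, name):
        v = row.get(name)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        v = str(v).strip()
        return v or None

    arms: list[TrialArm] = []
    contrasts: list[ContrastObservation] = []
    ref_of_trial: dict[str, str] = {}
    pending: list[tuple[int, dict]] = []

    for i, row in enumerate(df.to_dict("records")):
        rowno = i + 2  # header is line 1
        trial = cell(row, "trial_id")
        code = cell(row, "treatment")
        if trial is None or code is None:
            raise NetworkError(f"{path} row {rowno}: missing trial_id/treatment")
        if code not in treatments:
            raise NetworkError(
                f"{path} row {rowno}: unknown treatment code {code!r}"
            )
        try:
            n = int(cell(row, "n"))
        except (TypeError, ValueError):
            raise NetworkError(f"{path} row {rowno}: bad patient count") from None
        arms.append(
            TrialArm(
                trial_id=trial,
                treatment_id=code,
                n_enrolled=n,
                dose_label=cell(row, "dose_label") or "",
                ae_any=int(v) if (v := cell(row, "ae_any")) else None,
                ae_high=int(v) if (v := cell(row, "ae_high")) else None,
            )
        )
        hr = cell(row, "hr")
        outcome = cell(row, "outcome") or schema
        if hr is None:
            continue
        if hr.lower() == "ref":
            if ref_of_trial.setdefault(trial, code) != code:
                raise NetworkError(
                    f"{path} row {rowno}: trial {trial!r} has two reference arms"
                )
            continue
        pending.append(
            (
                rowno,
                {
                    "trial": trial,
                    "code": code,
                    "hr": hr,
                    "lo": cell(row, "ci_low"),
                    "hi": cell(row, "ci_high"),
                    "outcome": outcome,
                    "dose": cell(row, "dose_label") or "",
                },
            )
        )

    for rowno, p in pending:
        if p["trial"] not in ref_of_trial:
            raise NetworkError(
                f"{path} row {rowno}: trial {p['trial']!r} reports an HR "
                "but has no reference arm"
            )
        try:
            hr = float(p["hr"])
            lo, hi = float(p["lo"]), float(p["hi"])
        except (TypeError, ValueError):
            raise NetworkError(
                f"{path} row {rowno}: malformed HR/CI cells"
            ) from None
        if not 0 < lo < hi:
            raise NetworkError(
                f"{path} row {rowno}: malformed CI ({lo}, {hi}): "
                "bounds must be positive with lower < upper"
            )
        contrasts.append(
            ContrastObservation(
                trial_id=p["trial"],
                baseline=ref_of_trial[p["trial"]],
                comparator=p["code"],
                outcome=p["outcome"],
                y=math.log(hr),
                se=se_from_ci(lo, hi),
                dose_label=p["dose"],
            )
        )

    return EvidenceNetwork(dict(treatments), arms, contrasts).validate()


def write_trial_table(
    network: EvidenceNetwork, path: str | Path, level: float = 0.95
) -> None:
    """Emit a network in the per-arm delimited format ``load_trial_table``
    ingests (reference arms as ``ref``, contrasts as HR with a CI whose width
    reproduces the stored se)."""
    z = norm.ppf(0.5 * (1.0 + level))
    by_arm: dict[tuple[str, str, str], ContrastObservation] = {}
    ref_of: dict[str, str] = {}
    for c in network.contrasts:
        by_arm[(c.trial_id, c.comparator, c.dose_label)] = c
        ref_of[c.trial_id] = c.baseline
    rows = []
    for a in network.arms:
        c = by_arm.get((a.trial_id, a.treatment_id, a.dose_label))
        if c is not None:
            hr = f"{math.exp(c.y):.10g}"
            lo = f"{math.exp(c.y - z * c.se):.10g}"
            hi = f"{math.exp(c.y + z * c.se):.10g}"
            outcome = c.outcome
        elif ref_of.get(a.trial_id) == a.treatment_id:
            hr, lo, hi, outcome = "ref", "", "", ""
        else:
            hr, lo, hi, outcome = "", "", "", ""
        rows.append(
            {
                "trial_id": a.trial_id,
                "author_year": "",
                "treatment": a.treatment_id,
                "n": a.n_enrolled,
                "hr": hr,
                "ci_low": lo,
                "ci_high": hi,
                "ae_any": "" if a.ae_any is None else a.ae_any,
                "ae_high": "" if a.ae_high is None else a.ae_high,
                "outcome": outcome,
                "dose_label": a.dose_label,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_risk_flags(path: str | Path) -> RiskFlags:
    """Read the trial_id,low_risk flag table (booleans as 0/1 or true/false)."""
    df = pd.read_csv(path, dtype=str, comment="#")
    flags = {}
    for _, row in df.iterrows():
        v = str(row["low_risk"]).strip().lower()
        flags[str(row["trial_id"]).strip()] = v in ("1", "true", "yes")
    return RiskFlags(flags)


def merge_dose_arms(network: EvidenceNetwork, policy: str = "pool") -> EvidenceNetwork:
    """Collapse same-treatment dose arms within a trial.

    ``pool`` combines the dose contrasts against the shared baseline by
    inverse-variance fixed-effect pooling on the log scale and sums enrolments;
    ``keep_first`` retains the first-listed dose arm; ``keep_all_as_distinct``
    returns the network unchanged.
    """
    if policy == "keep_all_as_distinct":
        return network
    if policy not in ("pool", "keep_first"):
        raise ValueError(f"unknown dose-arm policy {policy!r}")

    arms: list[TrialArm] = []
    contrasts: list[ContrastObservation] = []
    roster = network.trial_roster()

    for trial, trial_arms in roster.items():
        trial_contrasts = [c for c in network.contrasts if c.trial_id == trial]
        by_treat: dict[str, list[TrialArm]] = {}
        for a in trial_arms:
            by_treat.setdefault(a.treatment_id, []).append(a)
        dup_treats = {t for t, group in by_treat.items() if len(group) > 1}
        if not dup_treats:
            arms.extend(trial_arms)
            contrasts.extend(trial_contrasts)
            continue
        baselines = {c.baseline for c in trial_contrasts}
        if policy == "pool" and dup_treats & baselines:
            raise NetworkError(
                f"trial {trial!r}: cannot pool dose arms of a baseline treatment"
            )
        for treat, group in by_treat.items():
            if treat not in dup_treats:
                arms.extend(group)
                continue
            if policy == "keep_first":
                arms.append(group[0])
                log.warning(
                    "trial %s: keep_first dropped %d extra %s dose arm(s)",
                    trial, len(group) - 1, treat,
                )
            else:
                merged = replace(
                    group[0],
                    n_enrolled=sum(a.n_enrolled for a in group),
                    dose_label="pooled: " + " | ".join(a.dose_label for a in group),
                    ae_any=(
                        sum(a.ae_any for a in group)
                        if all(a.ae_any is not None for a in group)
                        else None
                    ),
                    ae_high=(
                        sum(a.ae_high for a in group)
                        if all(a.ae_high is not None for a in group)
                        else None
                    ),
                )
                arms.append(merged)
        for outcome in OUTCOMES:
            oc = [c for c in trial_contrasts if c.outcome == outcome]
            by_pair: dict[tuple[str, str], list[ContrastObservation]] = {}
            for c in oc:
                by_pair.setdefault((c.baseline, c.comparator), []).append(c)
            for (b, k), group in by_pair.items():
                if len(group) == 1 or k not in dup_treats:
                    if policy == "keep_first" and k in dup_treats:
                        first_dose = by_treat[k][0].dose_label
                        group = [c for c in group if c.dose_label == first_dose]
                    contrasts.extend(group)
                elif policy == "keep_first":
                    first_dose = by_treat[k][0].dose_label
                    contrasts.extend(c for c in group if c.dose_label == first_dose)
                else:
                    y, se = _pool_iv([(c.y, c.se) for c in group])
                    contrasts.append(
                        replace(
                            group[0],
                            y=y,
                            se=se,
                            dose_label="pooled: "
                            + " | ".join(c.dose_label for c in group),
                        )
                    )

    return EvidenceNetwork(dict(network.treatments), arms, contrasts).validate()


def resolve_auxiliary_nodes(
    network: EvidenceNetwork, policy: str = "aux_node"
) -> EvidenceNetwork:
    """Handle trials anchored on a non-reportable (auxiliary) baseline node.

    ``aux_node`` keeps the auxiliary treatment as a likelihood-only node
    (preserving the trial's internal randomization); ``rebase_independent``
    re-anchors the trial on its first reportable comparator, differencing the
    two contrasts (y = y1 - y2, se = sqrt(se1^2 + se2^2); treats the two
    published contrasts as independent) and drops the auxiliary arm.
    """
    if policy == "aux_node":
        return network
    if policy != "rebase_independent":
        raise ValueError(f"unknown auxiliary-node policy {policy!r}")

    aux = {t.id for t in network.treatments.values() if not t.reportable}
    if not aux:
        return network

    arms = [a for a in network.arms if a.treatment_id not in aux]
    contrasts: list[ContrastObservation] = []
    by_trial: dict[tuple[str, str], list[ContrastObservation]] = {}
    for c in network.contrasts:
        by_trial.setdefault((c.trial_id, c.outcome), []).append(c)
    # comparators seen in trials not anchored on an auxiliary node: preferred
    # rebase targets, since they keep the trial connected to the network
    connected = set()
    for c in network.contrasts:
        if c.baseline not in aux:
            connected.add(c.baseline)
            if c.comparator not in aux:
                connected.add(c.comparator)
    order = {t: i for i, t in enumerate(network.treatments)}
    for (trial, _outcome), group in by_trial.items():
        if group[0].baseline not in aux:
            contrasts.extend(group)
            continue
        candidates = sorted(
            (c for c in group if c.comparator not in aux),
            key=lambda c: (c.comparator not in connected, order[c.comparator]),
        )
        anchor = candidates[0] if candidates else None
        others = [c for c in group if c is not anchor]
        if anchor is None:
            continue  # trial entirely auxiliary: contributes nothing reportable
        for c in others:
            contrasts.append(
                replace(
                    c,
                    baseline=anchor.comparator,
                    y=c.y - anchor.y,
                    se=(c.se**2 + anchor.se**2) ** 0.5,
                )
            )
    kept_treats = {
        t: tr for t, tr in network.treatments.items() if t not in aux
    }
    return EvidenceNetwork(kept_treats, arms, contrasts).validate()


def filter_low_risk(network: EvidenceNetwork, flags: RiskFlags) -> EvidenceNetwork:
    """Restrict to low-risk-of-bias trials; refuses a disconnected result."""
    flags.require_cover(network)
    keep = {t for t, low in flags.flags.items() if low}
    arms = [a for a in network.arms if a.trial_id in keep]
    contrasts = [c for c in network.contrasts if c.trial_id in keep]
    out = EvidenceNetwork(dict(network.treatments), arms, contrasts).validate()
    for outcome in OUTCOMES:
        if out.contrasts_for(outcome):
            out.require_connected(outcome)
    return out
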