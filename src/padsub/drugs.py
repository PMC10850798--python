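"""Cross-study drug-vulnerability calling for subtyped cell lines.

For every (study, subtype, drug) with at least ``min_lines`` tested cell
lines, the mean AAC (area above the dose-response curve, in [0, 1]) is
computed.  Within each study, a (subtype, drug) is flagged when its mean
exceeds the study-wide mean of those subtype-level means plus two standard
deviations.  A vulnerability is called when the pair is flagged in at least
``min_studies`` studies and the drug is differential, i.e. at least one
other subtype with computed means for the drug is not itself called.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ValidationError

logger = logging.getLogger(__name__)


def subtype_drug_means(
    panel: pd.DataFrame,
    labels: pd.Series,
    min_lines: int = 2,
) -> pd.DataFrame:
    """Mean AAC per (study, subtype, drug), keeping entries with >= min_lines.

    ``panel`` is long-format (study, cell_line, drug, aac); ``labels`` maps
    cell line to subtype.  Cell lines without a label are ignored.
    """
    if min_lines < 2:
        raise ValidationError("min_lines must be >= 2")
    df = panel.copy()
    df["subtype"] = df["cell_line"].map(labels)
    df = df.dropna(subset=["subtype"])
    grouped = df.groupby(["study", "subtype", "drug"])["aac"].agg(["mean", "count"])
    grouped = grouped[grouped["count"] >= min_lines].reset_index()
    return grouped.rename(columns={"mean": "mean_aac", "count": "n_lines"})


def study_threshold(study_means: pd.Series | np.ndarray) -> float:
    """Mean + 2 SD over a study's computed subtype-level mean AACs.

    The SD uses the n-1 denominator.  Fewer than two values leave the
    threshold undefined (the study is excluded, with a warning upstream).
    """
    vals = np.asarray(study_means, dtype=float)
    if len(vals) < 2:
        raise ValidationError("need >= 2 mean values to set a threshold")
    return float(vals.mean() + 2.0 * vals.std(ddof=1))


@dataclass
class VulnerabilityCall:
    """A (subtype, drug) pair called sensitive across studies."""

    subtype: str
    drug: str
    n_flagging_studies: int
    per_study: pd.DataFrame     # study, mean_aac, n_lines, flagged
    differential: bool


def call_vulnerabilities(
    panel: pd.DataFrame,
    labels: pd.Series,
    min_lines: int = 2,
    min_studies: int = 2,
) -> list[VulnerabilityCall]:
    """Apply the cross-study mean + 2 SD rule and the differential filter.

    A pair is called when flagged in >= ``min_studies`` studies and at
    least one other subtype with computed means for the same drug does not
    itself reach the flagging criterion.
    """
    means = subtype_drug_means(panel, labels, min_lines=min_lines)
    studies = sorted(panel["study"].unique())
    if len(studies) < min_studies:
        raise ValidationError(
            f"panel has {len(studies)} studies, fewer than min_studies={min_studies}"
        )
    flagged_frames = []
    for study in studies:
        block = means[means["study"] == study]
        if len(block) < 2:
            logger.warning("study %s has < 2 subtype-drug means; excluded", study)
            continue
        thr = study_threshold(block["mean_aac"])
        block = block.copy()
        block["flagged"] = block["mean_aac"] > thr
        flagged_frames.append(block)
    if not flagged_frames:
        return []
    flagged = pd.concat(flagged_frames, ignore_index=True)
    n_flags = (
        flagged[flagged["flagged"]]
        .groupby(["subtype", "drug"]).size()
    )
    passing = set(n_flags.index[n_flags >= min_studies])
    calls: list[VulnerabilityCall] = []
    for subtype, drug in sorted(passing):
        others = flagged[(flagged["drug"] == drug) & (flagged["subtype"] != subtype)]
        other_subtypes = set(others["subtype"])
        differential = any(
            (s, drug) not in passing for s in other_subtypes
        ) and bool(other_subtypes)
        if not differential:
            continue
        per_study = flagged[
            (flagged["subtype"] == subtype) & (flagged["drug"] == drug)
        ][["study", "mean_aac", "n_lines", "flagged"]].reset_index(drop=True)
        calls.append(VulnerabilityCall(
            subtype=subtype, drug=drug,
            n_flagging_studies=int(n_flags.loc[(subtype, drug)]),
            per_study=per_study, differential=True,
        ))
    return calls


def calls_to_frame(calls: list[VulnerabilityCall]) -> pd.DataFrame:
    rows = [{
        "subtype": c.subtype, "drug": c.drug,
        "n_flagging_studies": c.n_flagging_studies,
        "mean_aac": c.per_study["mean_aac"].mean(),
    } for c in calls]
    return pd.DataFrame(rows, columns=["subtype", "drug",
                                       "n_flagging_studies", "mean_aac"])
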