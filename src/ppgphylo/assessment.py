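"""Per-session influence assessment and the multi-participant consensus table.

A care session yields four signals: the care-giver's recording made during
the session and the participant's recordings before, during and after it.
For each of three distortion measures — Itakura (symmetrized for the
matrix), root-mean-square log spectral, and weighted cepstral — the 4x4
dissimilarity matrix is built, its UPGMA tree reconstructed, and the
measure "supports" the care-giver's influence when the Care-giver and
During-care leaves form a cherry (a two-leaf clade). The consensus is the
percentage of the three measures that support, rounded to an integer
(0 / 33 / 67 / 100).

An optional relaxed rule also counts a measure as supporting when the
Care-giver leaf's sibling subtree contains During care (the care-giver
attaches next to a clade that includes the during-session signal). It is
disabled by default and always reported separately from the strict rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .distortion import DistortionConfig, dissimilarity_matrix
from .signal_io import SESSION_LABELS, Signal
from .upgma import Tree, is_cherry, sibling_subtree_labels, upgma

__all__ = [
    "ASSESSED_MEASURES",
    "SessionAssessment",
    "assess_session",
    "assess_raw_session",
    "consensus_table",
    "assess_bundles",
]

#: The three measures entering the consensus, in reporting order.
ASSESSED_MEASURES = ("ID", "LSD", "WCD")

CAREGIVER, BEFORE, DURING, AFTER = SESSION_LABELS


@dataclass(frozen=True)
class SessionAssessment:
    """One participant's assessment: per-measure support and the consensus."""

    participant_id: str
    support: dict[str, bool]  # measure -> strict-cherry support flag
    newick: dict[str, str]  # measure -> tree
    trees: dict[str, Tree] = field(repr=False, default=None)  # type: ignore[assignment]
    relaxed_support: dict[str, bool] | None = None

    @property
    def supporting_methods(self) -> tuple[str, ...]:
        return tuple(m for m in ASSESSED_MEASURES if self.support[m])

    @property
    def consensus_pct(self) -> int:
        return round(100 * len(self.supporting_methods) / len(ASSESSED_MEASURES))

    @property
    def supporting_methods_text(self) -> str:
        return ", ".join(self.supporting_methods) or "None"


def assess_session(caregiver: Signal, before: Signal, during: Signal,
                   after: Signal, p: int = 12, grid: int = 1024,
                   participant_id: str = "", relaxed: bool = False,
                   ) -> SessionAssessment:
    """Assess one session under the three-measure strict-cherry rule.

    The four signals are relabelled to the canonical session labels
    (Care-giver, Before care, During care, After care) regardless of their
    incoming labels. Signals are used as given — callers preprocess raw
    recordings first. A degenerate signal raises an error naming which of
    the four it is.
    """
    signals = {
        label: Signal(sig.samples, label=label, sampling_rate=sig.sampling_rate)
        for label, sig in zip(SESSION_LABELS, (caregiver, before, during, after))
    }
    support: dict[str, bool] = {}
    relaxed_support: dict[str, bool] = {}
    newick: dict[str, str] = {}
    trees: dict[str, Tree] = {}
    for measure in ASSESSED_MEASURES:
        config = DistortionConfig(measure=measure, p=p, grid=grid)
        tree = upgma(dissimilarity_matrix(signals, config))
        trees[measure] = tree
        newick[measure] = tree.newick()
        support[measure] = is_cherry(tree, CAREGIVER, DURING)
        relaxed_support[measure] = support[measure] or (
            DURING in sibling_subtree_labels(tree, CAREGIVER)
        )
    return SessionAssessment(
        participant_id=participant_id,
        support=support,
        newick=newick,
        trees=trees,
        relaxed_support=relaxed_support if relaxed else None,
    )


def assess_raw_session(caregiver: Signal, before: Signal, during: Signal,
                       after: Signal, p: int = 12, grid: int = 1024,
                       participant_id: str = "", relaxed: bool = False,
                       preprocess_config: "PreprocessConfig | None" = None,
                       ) -> SessionAssessment:
    """Preprocess four raw recordings (detrend + smooth), then assess.

    Convenience wrapper for signals straight off a sensor or the synthetic
    generator; already-preprocessed data should go to :func:`assess_session`
    directly.
    """
    from .preprocess import PreprocessConfig, preprocess

    config = preprocess_config or PreprocessConfig()
    clean = [preprocess(s, config) for s in (caregiver, before, during, after)]
    return assess_session(*clean, p=p, grid=grid,
                          participant_id=participant_id, relaxed=relaxed)


def consensus_table(assessments: list[SessionAssessment]) -> pd.DataFrame:
    """Tabulate assessments, one row per participant, in input order.

    Columns: ``Participant ID#``, ``Consensus (%)``, ``Supporting
    method(s)``. Duplicate participant ids are an error.
    """
    ids = [a.participant_id for a in assessments]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate participant ids: {dupes}")
    return pd.DataFrame(
        {
            "Participant ID#": ids,
            "Consensus (%)": [a.consensus_pct for a in assessments],
            "Supporting method(s)": [a.supporting_methods_text for a in assessments],
        }
    )


def assess_bundles(caregiver: dict[str, Signal], before: dict[str, Signal],
                   during: dict[str, Signal], after: dict[str, Signal],
                   p: int = 12, grid: int = 1024) -> list[SessionAssessment]:
    """Assess every participant present in all four labelled signal mappings.

    Intended for supplementary-style bundles keyed by participant index; the
    caregiver mapping holds the care-giver recording synchronized with each
    participant's session.
    """
    common = [k for k in during if k in caregiver and k in before and k in after]
    if not common:
        raise ValueError("no participant present in all four bundles")
    return [
        assess_session(caregiver[k], before[k], during[k], after[k],
                       p=p, grid=grid, participant_id=k)
        for k in common
    ]
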