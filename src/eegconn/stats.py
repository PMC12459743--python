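"""Behavioral coding, connectivity statistics, and graph rendering.

Response coding follows the task rules: a Go trial is a hit if the correct
key arrives within 0-1700 ms, an error if a wrong key arrives in that
window, and a miss otherwise; a Nogo trial is a correct omission when no
response occurs within 1700 ms and a false alarm otherwise.  The Simon Nogo
effect is the accuracy difference Nogo-congruent minus Nogo-incongruent.
Connectivity comparisons use nonparametric rank tests (paired signed-rank
within group, rank-sum between groups), reported uncorrected at the chosen
alpha with correction left to the caller.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .syndata import (
    GO,
    NOGO,
    RESPONSE_WINDOW_MS,
    BehavioralRecord,
    TaskDesign,
    TrialEvent,
)

CONDITIONS = ["go_congruent", "go_incongruent", "nogo_congruent", "nogo_incongruent"]


# ---------------------------------------------------------------------------
# behavioral coding
# ---------------------------------------------------------------------------

def code_single_response(trial: TrialEvent, response: str, rt_ms: float | None) -> str:
    in_window = response != "none" and rt_ms is not None and 0.0 <= rt_ms <= RESPONSE_WINDOW_MS
    if trial.trial_type == GO:
        if not in_window:
            return "miss"
        return "hit" if response == trial.correct_response else "error"
    return "false_alarm" if in_window else "correct_omission"


def code_responses(design: TaskDesign, responses) -> list[BehavioralRecord]:
    """Code raw (trial_index, response, rt_ms) tuples against the design.

    Responses after the 1700 ms window count as absent.  The resulting
    outcomes partition trials exactly: hits + errors + misses = n_Go and
    correct omissions + false alarms = n_Nogo.
    """
    by_index = {t.index: t for t in design.trials}
    records = []
    for trial_index, response, rt_ms in responses:
        trial = by_index.get(int(trial_index))
        if trial is None:
            raise ValueError(f"response for unknown trial {trial_index}")
        outcome = code_single_response(trial, response, rt_ms)
        records.append(
            BehavioralRecord(int(trial_index), response,
                             rt_ms if response != "none" else None, outcome)
        )
    return records


def accuracy_table(records: list[BehavioralRecord], design: TaskDesign) -> pd.DataFrame:
    """Per-condition accuracy: Go hit rate, Nogo correct-omission rate."""
    by_index = {t.index: t for t in design.trials}
    correct = {c: 0 for c in CONDITIONS}
    total = {c: 0 for c in CONDITIONS}
    for rec in records:
        trial = by_index[rec.trial_index]
        key = f"{trial.trial_type}_{trial.congruency}"
        total[key] += 1
        if rec.outcome in ("hit", "correct_omission"):
            correct[key] += 1
    rows = []
    for key in CONDITIONS:
        acc = correct[key] / total[key] if total[key] else np.nan
        rows.append({"condition": key, "n_correct": correct[key],
                     "n_total": total[key], "accuracy": acc,
                     "defined": total[key] > 0})
    return pd.DataFrame(rows).set_index("condition")


def simon_nogo_effect(table: pd.DataFrame) -> float:
    """Accuracy(Nogo congruent) - accuracy(Nogo incongruent).

    Negative under the typical inversion of the Simon effect on Nogo trials
    (the prepotent congruent response is harder to withhold).
    """
    cong = table.loc["nogo_congruent"]
    incong = table.loc["nogo_incongruent"]
    if not (cong.defined and incong.defined):
        raise ValueError("Simon Nogo effect undefined: empty Nogo cell")
    return float(cong.accuracy - incong.accuracy)


def behavioral_frame(records: list[BehavioralRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial": [r.trial_index for r in records],
            "response": [r.response for r in records],
            "rt_ms": [r.rt_ms if r.rt_ms is not None else np.nan for r in records],
            "outcome": [r.outcome for r in records],
        }
    )


# ---------------------------------------------------------------------------
# connectivity statistics
# ---------------------------------------------------------------------------

def direction_asymmetry_test(values_ij, values_ji, alpha: float = 0.05) -> dict:
    """Paired two-sided signed-rank test between the two flow directions.

    ``values_ij``/``values_ji`` are per-subject connectivity values for
    i->j and j->i.  Returns p, the dominant direction ("ij", "ji" or "none"),
    and the significance flag at ``alpha``.
    """
    a = np.asarray(values_ij, dtype=float)
    b = np.asarray(values_ji, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 6:
        raise ValueError("need at least 6 subjects for the signed-rank test")
    diff = a - b
    if np.allclose(diff, 0.0):
        p = 1.0
    else:
        p = float(spstats.wilcoxon(a, b, zero_method="wilcox", method="auto").pvalue)
    direction = "ij" if a.mean() > b.mean() else ("ji" if b.mean() > a.mean() else "none")
    return {"p": p, "direction": direction, "significant": bool(p < alpha)}


def network_strength(conn, include_self: bool = False) -> float:
    """Mean connectivity over the network (off-diagonal entries by default)."""
    mat = np.asarray(conn.lc if hasattr(conn, "lc") else conn, dtype=float)
    if mat.shape[0] < 2:
        raise ValueError("network strength needs at least 2 nodes")
    if include_self:
        return float(mat.mean())
    off = ~np.eye(mat.shape[0], dtype=bool)
    return float(mat[off].mean())


def compare_strength(group_a, group_b, paired: bool = False) -> dict:
    """Rank test between two samples of per-subject network strengths."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if min(a.size, b.size) < 3:
        raise ValueError("need at least 3 values per sample")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison needs equal lengths")
        if np.allclose(a, b):
            return {"p": 1.0, "statistic": 0.0}
        res = spstats.wilcoxon(a, b, method="auto")
    else:
        res = spstats.mannwhitneyu(a, b, alternative="two-sided")
    return {"p": float(res.pvalue), "statistic": float(res.statistic)}


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_connectivity_graph(
    node_names: list[str],
    node_positions: np.ndarray,
    conn: np.ndarray,
    masks: np.ndarray | None,
    out_path,
    title: str = "",
    color: str = "tab:blue",
) -> None:
    """Schematic directed-connectivity plot written as a deterministic SVG.

    One node per cluster at its (2-D projected) centroid; each off-diagonal
    value is drawn as a curved arrow whose width scales with the value and
    whose label is the value x 100 rounded to two decimals.  Solid arrows
    mark entries flagged by ``masks``; dashed arrows mark the rest.
    Rendering twice from the same inputs yields byte-identical files.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    conn = np.asarray(conn, dtype=float)
    n = len(node_names)
    if conn.shape != (n, n):
        raise ValueError("connectivity matrix does not match node count")
    pos = np.asarray(node_positions, dtype=float)[:, :2]
    if pos.shape[0] != n:
        raise ValueError("node positions do not match node count")
    if masks is None:
        masks = np.zeros_like(conn, dtype=bool)

    with plt.rc_context({"svg.hashsalt": "eegconn"}):
        fig, ax = plt.subplots(figsize=(5, 5))
        span = max(np.ptp(pos[:, 0]), np.ptp(pos[:, 1]), 1.0)
        vmax = max(conn.max(), 1e-12)
        for j in range(n):
            for i in range(n):
                if i == j or conn[j, i] <= 0:
                    continue
                ax.annotate(
                    "",
                    xy=pos[j], xytext=pos[i],
                    arrowprops=dict(
                        arrowstyle="-|>",
                        connectionstyle="arc3,rad=0.15",
                        linewidth=0.5 + 2.5 * conn[j, i] / vmax,
                        linestyle="solid" if masks[j, i] else (0, (4, 3)),
                        color=color,
                        shrinkA=14, shrinkB=14,
                    ),
                )
                mid = 0.5 * (pos[i] + pos[j])
                offset = 0.11 * span * np.sign(pos[j] - pos[i])[::-1] * (1, -1)
                ax.text(*(mid + offset), f"{100.0 * conn[j, i]:.2f}",
                        ha="center", va="center", fontsize=8, color=color)
        for k, name in enumerate(node_names):
            ax.scatter(*pos[k], s=700, facecolor="white", edgecolor="black", zorder=3)
            ax.text(*pos[k], name, ha="center", va="center", fontsize=8, zorder=4)
        ax.set_title(title)
        ax.set_aspect("equal")
        ax.margins(0.2)
        ax.axis("off")
        fig.savefig(out_path, format="svg", metadata={"Date": None})
        plt.close(fig)
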