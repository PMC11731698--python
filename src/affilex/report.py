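"""Regression report tables and bipartite network exports.

The regression report mirrors the field's standard layout: one row per
communication theme x communication style, cells ``b (SE)`` with footnote
markers a/b/c for p < .001 / .01 / .05.  Network exports are attributed
bipartite graphs (GEXF primarily, GraphML as an alternative) suitable for
Gephi-style external visualization: user nodes carry persona fields,
engagement and engagement tier; speech-act nodes are the second mode; edge
weights are affiliation counts.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Optional, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd

from .nam import NamFit
from .network import AffiliationMatrix
from .records import UserPersona
from .vocab import Theme

#: Footnote convention: a = p<.001, b = p<.01, c = p<.05.
SIGNIFICANCE_LEVELS = (("a", 0.001), ("b", 0.01), ("c", 0.05))


def significance_marker(p: float) -> str:
    if p is None or not np.isfinite(p):
        return ""
    for marker, level in SIGNIFICANCE_LEVELS:
        if p < level:
            return marker
    return ""


def _cell(est: float, se: float, p: float, decimals: int = 3) -> str:
    return f"{est:.{decimals}f}{significance_marker(p)} ({se:.{decimals}f})"


REPORT_COLUMNS = [
    "n",
    "affiliation_exposure",
    "medication",
    "diagnosis",
    "lifestyle",
    "sas_affiliated",
]


def regression_report(
    fits: Union[Mapping[tuple, NamFit], Sequence[NamFit]],
    decimals: int = 3,
) -> pd.DataFrame:
    """Render fitted models as a theme-by-style coefficient table.

    ``fits`` is a mapping ``(theme, style) -> NamFit`` or a sequence of
    labeled fits (label ``"theme:style"``).  Columns: the autocorrelation
    (affiliation exposure) coefficient, the three persona covariates, and
    the affiliated-act count, each as ``b (SE)`` with significance markers;
    plus the per-network n.  An empty input yields an empty table with the
    same headers.
    """
    if isinstance(fits, Mapping):
        items = [(k[0], k[1], f) for k, f in fits.items()]
    else:
        items = []
        for f in fits:
            theme, _, style = (f.label or "?:?").partition(":")
            items.append((theme, style, f))

    rows = []
    index = []
    for theme, style, fit in items:
        tname = theme.value if isinstance(theme, Theme) else str(theme)
        index.append((tname, style))
        row = {"n": fit.n, "affiliation_exposure": _cell(fit.rho, fit.rho_se, fit.rho_p, decimals)}
        for cov in ("medication", "diagnosis", "lifestyle"):
            if cov in fit.coef.index:
                r = fit.coef.loc[cov]
                row[cov] = _cell(r["estimate"], r["se"], r["p"], decimals)
            else:
                row[cov] = ""
        row["sas_affiliated"] = _cell(fit.gamma, fit.gamma_se, fit.gamma_p, decimals)
        rows.append(row)

    table = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["theme", "style"])
        if index
        else pd.MultiIndex.from_tuples([], names=["theme", "style"]),
        columns=REPORT_COLUMNS,
    )
    return table


def report_text(table: pd.DataFrame) -> str:
    """Aligned plain-text rendering with the significance footnote."""
    body = table.to_string()
    legend = "; ".join(f"{m}: p < {lvl}" for m, lvl in SIGNIFICANCE_LEVELS)
    return f"{body}\n\nSignificance markers: {legend}\n"


@dataclasses.dataclass
class EngagementTiers:
    """Three posting-frequency tiers partitioning a network's users.

    ``low`` and ``high`` are the two cutoffs: engagement below ``low`` is
    infrequent, at or above ``high`` is power, in between sustained.
    Defaults to tertiles of the engagement distribution.
    """

    low: float
    high: float

    def __post_init__(self):
        if self.high < self.low:
            raise ValueError("tier cutoffs must be monotone (low <= high)")

    @classmethod
    def tertiles(cls, engagement: pd.Series) -> "EngagementTiers":
        lo, hi = np.quantile(engagement.to_numpy(dtype=float), [1 / 3, 2 / 3])
        return cls(low=float(lo), high=float(hi))

    def classify(self, value: float) -> str:
        if value >= self.high:
            return "power"
        if value >= self.low:
            return "sustained"
        return "infrequent"


def export_network(
    matrix: AffiliationMatrix,
    personas: Optional[Sequence[UserPersona]] = None,
    engagement: Optional[pd.Series] = None,
    tiers: Optional[EngagementTiers] = None,
) -> nx.Graph:
    """Build the attributed bipartite graph of one theme network.

    Nodes carry ``mode`` (``user`` / ``speech_act``); user nodes carry
    persona axes, engagement, and tier; an edge exists for every nonzero
    count cell, weighted by the count.
    """
    persona_by_user = {p.user_id: p for p in (personas or [])}
    if engagement is not None and tiers is None and len(engagement):
        tiers = EngagementTiers.tertiles(engagement)

    G = nx.Graph()
    G.graph["theme"] = matrix.theme.value
    for u in matrix.users:
        attrs = {"mode": "user", "bipartite": 0}
        p = persona_by_user.get(u)
        if p is not None:
            attrs.update(
                medication_status=p.medication_status.value,
                diagnosis_status=p.diagnosis_status.value,
                lifestyle_status=p.lifestyle_status.value,
            )
        if engagement is not None and u in engagement.index:
            e = float(engagement[u])
            attrs["engagement"] = e
            if tiers is not None:
                attrs["tier"] = tiers.classify(e)
        G.add_node(u, **attrs)
    for act in matrix.speech_acts:
        G.add_node(act.value, mode="speech_act", bipartite=1)
    for i, u in enumerate(matrix.users):
        for j, act in enumerate(matrix.speech_acts):
            w = int(matrix.counts[i, j])
            if w > 0:
                G.add_edge(u, act.value, weight=w)
    return G


def write_network(G: nx.Graph, path, format: str = "gexf") -> None:
    if format == "gexf":
        nx.write_gexf(G, path)
    elif format == "graphml":
        nx.write_graphml(G, path)
    else:
        raise ValueError(f"unknown graph format {format!r}")
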