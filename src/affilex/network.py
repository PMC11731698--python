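"""Two-mode user-by-speech-act affiliation networks and affiliation exposure.

Pipeline for one communication theme and one speech-act subset (a
communication style or the full vocabulary):

1. count matrix — ``counts[i, k]`` = messages by user *i* carrying the theme
   and speech act *k* (a multi-label message increments every act it
   carries); users with no message in the theme are excluded;
2. binarization — a user is *affiliated* with an act if the count reaches
   the network's median positive count (``A[i, k] = 1`` iff
   ``counts[i, k] >= threshold``);
3. coaffiliation — ``C = A Aᵀ``: off-diagonals count acts a user pair
   coexpresses, the diagonal ``D`` counts each user's affiliated acts;
4. exposure — ``F_i = Σ_{j≠i} C_ij y_j / Σ_{j≠i} C_ij``, the
   coaffiliation-weighted mean of peers' engagement, diagonal excluded.

Users whose off-diagonal coaffiliation row is all zero (isolates) get
exposure 0 and are flagged; they stay in downstream regressions by default.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import EmptyNetworkError
from .records import MessageRecord
from .vocab import Bct, SpeechAct, Theme, speech_act_order


@dataclasses.dataclass
class AffiliationMatrix:
    """User-by-speech-act matrix for one theme (counts and binary forms)."""

    theme: Union[Theme, Bct]
    users: list[str]
    speech_acts: list[SpeechAct]
    counts: np.ndarray
    binary: Optional[np.ndarray] = None
    threshold: Optional[float] = None

    @property
    def n(self) -> int:
        return len(self.users)

    @property
    def k(self) -> int:
        return len(self.speech_acts)

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=self.users,
            columns=[a.value for a in self.speech_acts],
        )

    def binary_frame(self) -> pd.DataFrame:
        if self.binary is None:
            raise ValueError("matrix not binarized yet")
        return pd.DataFrame(
            self.binary,
            index=self.users,
            columns=[a.value for a in self.speech_acts],
        )


@dataclasses.dataclass
class CoaffiliationMatrix:
    """Symmetric user-by-user shared-affiliation matrix C = A Aᵀ."""

    users: list[str]
    C: np.ndarray

    @property
    def D(self) -> np.ndarray:
        """Per-user affiliation count (diagonal of C)."""
        return np.diag(self.C).copy()

    def offdiag(self) -> np.ndarray:
        off = self.C.astype(float).copy()
        np.fill_diagonal(off, 0.0)
        return off

    def isolates(self) -> np.ndarray:
        """Boolean mask of users with an all-zero off-diagonal row."""
        return self.offdiag().sum(axis=1) == 0

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.C, index=self.users, columns=self.users)


def build_count_matrix(
    corpus: Sequence[MessageRecord],
    theme: Union[Theme, Bct],
    sa_subset: Optional[Iterable[SpeechAct]] = None,
    users: Optional[Iterable[str]] = None,
) -> AffiliationMatrix:
    """Count matrix of one theme's (or BCT's) user-by-speech-act affiliations.

    ``sa_subset`` restricts the event mode to a communication style; columns
    follow vocabulary declaration order.  ``users`` optionally restricts the
    user mode (e.g. the signature subset).  A user enters the matrix if they
    have at least one message in the theme, even if none of their messages
    carry an act from ``sa_subset`` (their row is then all zero).
    """
    acts = speech_act_order(sa_subset)
    col = {a: j for j, a in enumerate(acts)}
    allowed = set(users) if users is not None else None

    if isinstance(theme, Bct):
        in_theme = lambda r: theme in r.bcts  # noqa: E731
    else:
        in_theme = lambda r: theme in r.themes  # noqa: E731

    user_index: dict[str, int] = {}
    rows: list[np.ndarray] = []
    for r in corpus:
        if not in_theme(r):
            continue
        if allowed is not None and r.user_id not in allowed:
            continue
        if r.user_id not in user_index:
            user_index[r.user_id] = len(rows)
            rows.append(np.zeros(len(acts), dtype=int))
        row = rows[user_index[r.user_id]]
        for act in r.speech_acts:
            j = col.get(act)
            if j is not None:
                row[j] += 1

    if not user_index:
        raise EmptyNetworkError(f"no users have messages in theme {theme.value!r}")

    counts = np.vstack(rows) if rows else np.zeros((0, len(acts)), dtype=int)
    return AffiliationMatrix(
        theme=theme, users=list(user_index), speech_acts=acts, counts=counts
    )


def binarize(
    matrix: AffiliationMatrix, median_base: str = "positive"
) -> AffiliationMatrix:
    """Dichotomize a count matrix at the within-network median count.

    The threshold is the median of the matrix's positive cell counts (zeros
    are non-expression, not an expression count); ``median_base="all"``
    includes zeros instead.  Affiliation uses ``>=``, so ties at the median
    become 1.  The threshold is stored on the matrix for reporting.
    """
    counts = matrix.counts
    if median_base == "positive":
        base = counts[counts > 0]
    elif median_base == "all":
        base = counts.ravel()
    else:
        raise ValueError(f"unknown median_base {median_base!r}")
    if base.size == 0 or counts.max() == 0:
        raise EmptyNetworkError(
            f"all-zero count matrix for theme {matrix.theme.value!r}"
        )
    threshold = float(np.median(base))
    matrix.threshold = threshold
    matrix.binary = (counts >= threshold).astype(int)
    return matrix


def coaffiliation(matrix: AffiliationMatrix) -> CoaffiliationMatrix:
    """Coaffiliation matrix C = A Aᵀ from the binarized affiliation matrix."""
    if matrix.binary is None:
        raise ValueError("binarize the affiliation matrix first")
    A = matrix.binary
    return CoaffiliationMatrix(users=list(matrix.users), C=A @ A.T)


def affiliation_exposure(
    C: Union[CoaffiliationMatrix, np.ndarray],
    y: Union[pd.Series, np.ndarray],
    isolate_policy: str = "zero",
) -> pd.Series:
    """Affiliation exposure F_i = Σ_{j≠i} C_ij y_j / Σ_{j≠i} C_ij.

    The coaffiliation-weighted mean of peers' behavioral attribute
    (engagement), diagonal excluded.  Isolates get exposure 0 by default
    (``isolate_policy="zero"``) or NaN (``"nan"``); callers that drop
    isolates filter on the NaN form.

    ``C`` and ``y`` must share user order; when both carry labels they are
    checked.
    """
    if isinstance(C, CoaffiliationMatrix):
        users = C.users
        M = C.C
    else:
        users = None
        M = np.asarray(C)
    if isinstance(y, pd.Series):
        if users is not None and list(y.index) != list(users):
            raise ValueError("user order of C and y differs")
        yv = y.to_numpy(dtype=float)
    else:
        yv = np.asarray(y, dtype=float)
    if M.shape[0] != M.shape[1] or M.shape[0] != yv.shape[0]:
        raise ValueError("C must be square and aligned with y")

    off = M.astype(float).copy()
    np.fill_diagonal(off, 0.0)
    denom = off.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (off @ yv) / denom
    if isolate_policy == "zero":
        F[denom == 0] = 0.0
    elif isolate_policy == "nan":
        F[denom == 0] = np.nan
    else:
        raise ValueError(f"unknown isolate_policy {isolate_policy!r}")
    return pd.Series(F, index=users if users is not None else range(len(yv)), name="exposure")
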