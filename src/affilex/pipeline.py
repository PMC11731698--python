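"""End-to-end wiring: corpus -> theme/style network -> exposure -> model fit.

One fit per communication theme x communication style follows the study
design: restrict to the signature (persona) users, build the theme's
user-by-speech-act count matrix over the style's acts, binarize at the
median positive count, form C = A Aᵀ, row-normalize into W, and fit the
network autocorrelation model of posting frequency on persona covariates
and the affiliated-act count D.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .corpus import compute_engagement
from .errors import EmptyNetworkError
from .nam import NamFit, fit_nam, row_normalize
from .network import binarize, build_count_matrix, coaffiliation
from .records import (
    DiagnosisStatus,
    LifestyleStatus,
    MedicationStatus,
    MessageRecord,
    UserPersona,
)
from .vocab import Theme
from .synth import STYLE_SUBSETS

_ANY_MEDICATION = {
    MedicationStatus.ORAL_ONLY,
    MedicationStatus.INJECTABLE_ONLY,
    MedicationStatus.BOTH,
}


def encode_personas(personas: Sequence[UserPersona]) -> pd.DataFrame:
    """Design matrix (intercept + one binary column per persona axis).

    medication: any medication use = 1 (no medications / no information = 0);
    diagnosis: pre-existing = 1 (newly diagnosed / no information = 0);
    lifestyle: changes incorporated = 1.  Users without information stay in
    the fit, coded 0.
    """
    return pd.DataFrame(
        {
            "intercept": 1.0,
            "medication": [
                float(p.medication_status in _ANY_MEDICATION) for p in personas
            ],
            "diagnosis": [
                float(p.diagnosis_status is DiagnosisStatus.PRE_EXISTING)
                for p in personas
            ],
            "lifestyle": [
                float(p.lifestyle_status is LifestyleStatus.YES) for p in personas
            ],
        },
        index=[p.user_id for p in personas],
    )


def fit_theme_style(
    corpus: Sequence[MessageRecord],
    personas: Sequence[UserPersona],
    theme: Theme,
    style: str,
    engagement: Optional[pd.Series] = None,
    median_base: str = "positive",
    log_engagement: bool = False,
) -> NamFit:
    """Build one theme-by-style network and fit the autocorrelation model.

    ``style`` is ``"push_in"``, ``"interactive_turn_taking"``, or ``"all"``.
    Engagement defaults to each persona user's total posting frequency over
    the whole window; ``log_engagement`` applies log1p before fitting.
    """
    persona_users = [p.user_id for p in personas]
    if engagement is None:
        engagement = compute_engagement(corpus, users=persona_users)

    subset = None if style == "all" else STYLE_SUBSETS[style]
    aff = build_count_matrix(corpus, theme, sa_subset=subset, users=persona_users)
    binarize(aff, median_base=median_base)
    coaff = coaffiliation(aff)
    W = row_normalize(coaff)

    y = engagement.reindex(aff.users).to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("network contains users without engagement values")
    if log_engagement:
        y = np.log1p(y)

    X_all = encode_personas(personas)
    X = X_all.reindex(aff.users)
    if X.isna().any().any():
        raise ValueError("network contains users without personas")

    fit = fit_nam(
        y,
        W,
        X.to_numpy(),
        coaff.D.astype(float),
        names=list(X.columns),
        label=f"{theme.value}:{style}",
    )
    return fit


def fit_all(
    corpus: Sequence[MessageRecord],
    personas: Sequence[UserPersona],
    themes: Optional[Iterable[Theme]] = None,
    styles: Optional[Iterable[str]] = None,
    **kwargs,
) -> dict[tuple[Theme, str], NamFit]:
    """Fit every requested theme x style network (default: all 6 x 2).

    Themes with no affiliated users are skipped (they would raise
    :class:`EmptyNetworkError` individually).
    """
    themes = list(themes) if themes is not None else list(Theme)
    styles = list(styles) if styles is not None else list(STYLE_SUBSETS)
    fits: dict[tuple[Theme, str], NamFit] = {}
    for theme in themes:
        for style in styles:
            try:
                fits[(theme, style)] = fit_theme_style(
                    corpus, personas, theme, style, **kwargs
                )
            except EmptyNetworkError:
                continue
    return fits
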