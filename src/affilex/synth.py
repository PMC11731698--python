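"""Synthetic digital-health-community data with known ground truth.

The real forum corpus behind the analysis is not redistributable, so this
module generates data with the same statistical shape, in two modes:

* **corpus mode** — full message corpora: per-user Poisson posting counts,
  multi-label themes and speech acts with marginals anchored to the ADA
  community's descriptive tables, and templated signature strings rendered
  so that rule-based persona extraction provably recovers the sampled
  persona;
* **recovery mode** — network-autocorrelation instances with exact ground
  truth: a Bernoulli binary affiliation matrix, the derived coaffiliation
  and weight matrices, a persona design matrix, and an engagement vector
  simulated from the model at known (rho, beta, gamma, sigma).

A single seed expands into independent substreams (personas, messages,
noise) so subsystems are reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd

from . import reference
from .errors import ConfigError
from .network import AffiliationMatrix, CoaffiliationMatrix, coaffiliation
from .nam import WeightMatrix, row_normalize, simulate_nam
from .records import (
    DiagnosisStatus,
    LifestyleStatus,
    MedicationStatus,
    MessageRecord,
    UserPersona,
)
from .vocab import INTERACTIVE, PUSH_IN, SpeechAct, Theme, speech_act_order


def _normalize(d: dict) -> dict:
    total = float(sum(d.values()))
    if total <= 0:
        raise ConfigError("probability weights must have a positive sum")
    return {k: v / total for k, v in d.items()}


#: Multi-label speech-act inclusion anchors (labeled-subset prevalences;
#: unreported acts get a moderate default).
SA_PREVALENCE = {
    SpeechAct.ASSERTION: 0.563,
    SpeechAct.STATEMENT: 0.370,
    SpeechAct.DIRECTIVE: 0.261,
    SpeechAct.QUESTION: 0.203,
    SpeechAct.EMOTION: 0.150,
    SpeechAct.STANCE: 0.173,
    SpeechAct.DECLARATIVE: 0.150,
    SpeechAct.EXPRESSIVE: 0.150,
}
_IN_STYLE_BOOST = 1.0
_OUT_STYLE_DAMP = 0.3


@dataclasses.dataclass
class NamTruth:
    """Generating parameters of the network autocorrelation model."""

    rho: float = 0.3
    beta: tuple[float, ...] = (5.0, -0.5, 0.5, 0.5)  # intercept, med, dx, lifestyle
    gamma: float = 0.7
    sigma: float = 1.0


@dataclasses.dataclass
class GeneratorConfig:
    """Study conditions for the synthetic community.

    Defaults mirror the ADA community: 529 signature users posting at a mean
    rate of ~107.7 messages over 2014–2021 (≈57k messages), yearly and
    thematic marginals proportional to the published tables, and persona
    marginals from the published persona distribution (normalized, since the
    printed counts sum to 531 over 529 users).
    """

    seed: int
    n_users: int = reference.AEM_USERS
    years: tuple[int, int] = (2014, 2021)
    messages_per_user: float = reference.AEM_MESSAGES / reference.AEM_USERS
    year_weights: dict = dataclasses.field(
        default_factory=lambda: _normalize(reference.YEARLY_MESSAGES)
    )
    theme_weights: dict = dataclasses.field(
        default_factory=lambda: _normalize(reference.THEME_MESSAGES)
    )
    #: "categorical": one theme per message drawn from theme_weights.
    #: "bernoulli": multi-label inclusion with theme_inclusion probabilities
    #: (redrawn to guarantee >= 1 theme) — the ada-like setting.
    theme_mode: str = "categorical"
    theme_inclusion: dict = dataclasses.field(
        default_factory=lambda: {
            t: reference.THEME_MESSAGES[t] / reference.AEM_MESSAGES for t in Theme
        }
    )
    #: Mean per-user probability that a message is emitted in the
    #: interactive turn-taking style (vs push-in).
    sa_style_mix: float = 0.35
    n_topics: Optional[int] = None
    persona_marginals: dict = dataclasses.field(
        default_factory=lambda: {
            "medication": _normalize(reference.PERSONA_MEDICATION),
            "diagnosis": _normalize(reference.PERSONA_DIAGNOSIS),
            "lifestyle": _normalize(reference.PERSONA_LIFESTYLE),
        }
    )
    #: Probability that a rendered signature is corrupted (a sentence
    #: dropped), degrading persona recoverability.
    signature_noise: float = 0.0
    #: Recovery mode: per-(user, act) Bernoulli affiliation density.  At
    #: 0.25 a user is affiliated with ~2 of 8 acts, yielding a heterogeneous
    #: coaffiliation projection; as density grows toward saturation every
    #: row of W approaches the uniform average and the autocorrelation
    #: parameter loses identification.
    affiliation_density: float = 0.25
    nam_truth: NamTruth = dataclasses.field(default_factory=NamTruth)
    diagnosis_cutoff_year: int = 2018

    def validate(self) -> "GeneratorConfig":
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        for name, vec in (
            ("year_weights", self.year_weights),
            ("theme_weights", self.theme_weights),
            ("persona_marginals[medication]", self.persona_marginals["medication"]),
            ("persona_marginals[diagnosis]", self.persona_marginals["diagnosis"]),
            ("persona_marginals[lifestyle]", self.persona_marginals["lifestyle"]),
        ):
            if any(p < 0 for p in vec.values()):
                raise ConfigError(f"{name} has a negative probability")
            if abs(sum(vec.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1 (got {sum(vec.values())})")
        if self.messages_per_user <= 0:
            raise ConfigError("messages_per_user must be positive")
        if not 0.0 <= self.sa_style_mix <= 1.0:
            raise ConfigError("sa_style_mix must lie in [0, 1]")
        if not 0.0 <= self.affiliation_density <= 1.0:
            raise ConfigError("affiliation_density must lie in [0, 1]")
        if self.theme_mode not in ("categorical", "bernoulli"):
            raise ConfigError(f"unknown theme_mode {self.theme_mode!r}")
        if any(not 0.0 <= p <= 1.0 for p in self.theme_inclusion.values()):
            raise ConfigError("theme_inclusion probabilities must lie in [0, 1]")
        return self


def ada_like_config(seed: int, **overrides) -> GeneratorConfig:
    """The packaged fixture: 529 users with multi-label thematic structure."""
    cfg = GeneratorConfig(seed=seed, theme_mode="bernoulli", **overrides)
    return cfg.validate()


@dataclasses.dataclass
class SyntheticCorpus:
    messages: list[MessageRecord]
    personas: list[UserPersona]
    #: generator bookkeeping: realized posting count per user
    message_counts: pd.Series
    config: GeneratorConfig


_MONTHS = (
    "January", "February", "March", "April", "May", "June",
    "July", "August", "September", "October", "November", "December",
)


def _render_signature(
    persona: UserPersona, rng: np.random.Generator, cfg: GeneratorConfig
) -> str:
    """Render a forum signature that the extraction rules recover exactly."""
    parts: list[str] = []
    lo, hi = cfg.years
    if persona.diagnosis_status is DiagnosisStatus.PRE_EXISTING:
        year = int(rng.integers(1995, cfg.diagnosis_cutoff_year))
    elif persona.diagnosis_status is DiagnosisStatus.NEWLY_DIAGNOSED:
        year = int(rng.integers(cfg.diagnosis_cutoff_year, hi + 1))
    else:
        year = None
    if year is not None:
        if rng.random() < 0.5:
            parts.append(f"Diagnosed: {_MONTHS[rng.integers(12)]} {year}.")
        else:
            parts.append(f"Dx {year}.")

    med = persona.medication_status
    oral = f"Meds: {rng.choice(['metformin', 'glipizide'])} 500 mg twice a day."
    inj = f"{rng.choice(['Novolog', 'Lantus'])} 10 units at night."
    if med is MedicationStatus.ORAL_ONLY:
        parts.append(oral)
    elif med is MedicationStatus.INJECTABLE_ONLY:
        parts.append(inj)
    elif med is MedicationStatus.BOTH:
        parts.append(oral)
        parts.append(inj)
    elif med is MedicationStatus.NO_MEDICATIONS:
        if persona.lifestyle_status is LifestyleStatus.YES and rng.random() < 0.5:
            parts.append("I went diet controlled.")
        else:
            parts.append("No meds, just monitoring.")

    if persona.lifestyle_status is LifestyleStatus.YES:
        parts.append(
            str(
                rng.choice(
                    [
                        "Walking daily.",
                        "Low-carb diet.",
                        "Mediterranean diet.",
                        "Treadmill 30 minutes a day.",
                    ]
                )
            )
        )
    if not parts:
        parts.append("Hello from the forum.")

    if cfg.signature_noise > 0 and rng.random() < cfg.signature_noise and len(parts) > 1:
        del parts[rng.integers(len(parts))]
    return " ".join(parts)


def _sample_personas(
    cfg: GeneratorConfig, rng: np.random.Generator
) -> list[UserPersona]:
    users = [f"u{i:04d}" for i in range(cfg.n_users)]
    m = cfg.persona_marginals
    med_levels, med_p = zip(*m["medication"].items())
    dx_levels, dx_p = zip(*m["diagnosis"].items())
    ls_levels, ls_p = zip(*m["lifestyle"].items())
    personas = []
    for u in users:
        p = UserPersona(
            user_id=u,
            medication_status=med_levels[rng.choice(len(med_levels), p=med_p)],
            diagnosis_status=dx_levels[rng.choice(len(dx_levels), p=dx_p)],
            lifestyle_status=ls_levels[rng.choice(len(ls_levels), p=ls_p)],
        )
        sig = _render_signature(p, rng, cfg)
        personas.append(dataclasses.replace(p, signature_text=sig))
    return personas


def generate_corpus(config: GeneratorConfig) -> SyntheticCorpus:
    """Generate a full synthetic message corpus plus signature personas.

    Deterministic given ``config.seed``: per-user posting counts are
    Poisson, message years and themes follow the configured marginals, and
    each message's speech-act set comes from style-dependent Bernoulli
    inclusion (every message carries at least one act, biased toward the
    emitting user's communication style).
    """
    cfg = config.validate()
    ss = np.random.SeedSequence(cfg.seed).spawn(3)
    rng_personas = np.random.default_rng(ss[0])
    rng_msgs = np.random.default_rng(ss[1])

    personas = _sample_personas(cfg, rng_personas)
    users = [p.user_id for p in personas]

    counts = rng_msgs.poisson(cfg.messages_per_user, size=cfg.n_users)
    total = int(counts.sum())
    n_topics = cfg.n_topics or max(1, round(total / 8))

    # per-user interactive-style propensity, mean = sa_style_mix
    mix = np.clip(cfg.sa_style_mix, 1e-3, 1 - 1e-3)
    props = rng_msgs.beta(6.0 * mix, 6.0 * (1.0 - mix), size=cfg.n_users)

    user_of_msg = np.repeat(np.arange(cfg.n_users), counts)
    years_pool = sorted(cfg.year_weights)
    year_p = np.array([cfg.year_weights[y] for y in years_pool])
    msg_years = np.asarray(years_pool)[
        rng_msgs.choice(len(years_pool), size=total, p=year_p)
    ]
    msg_topics = rng_msgs.integers(n_topics, size=total)

    themes_pool = list(Theme)
    if cfg.theme_mode == "categorical":
        tw = np.array([cfg.theme_weights.get(t, 0.0) for t in themes_pool])
        tw = tw / tw.sum()
        primary = rng_msgs.choice(len(themes_pool), size=total, p=tw)
        theme_sets = [frozenset({themes_pool[i]}) for i in primary]
    else:
        inc = np.array([cfg.theme_inclusion.get(t, 0.0) for t in themes_pool])
        mat = rng_msgs.random((total, len(themes_pool))) < inc
        empty = ~mat.any(axis=1)
        if empty.any():  # guarantee >= 1 theme
            forced = rng_msgs.choice(
                len(themes_pool), size=int(empty.sum()), p=inc / inc.sum()
            )
            mat[np.where(empty)[0], forced] = True
        theme_sets = [
            frozenset(themes_pool[j] for j in np.where(row)[0]) for row in mat
        ]

    acts = list(SpeechAct)
    prevalence = np.array([SA_PREVALENCE[a] for a in acts])
    in_push = np.array([a in PUSH_IN for a in acts])
    style_interactive = rng_msgs.random(total) < props[user_of_msg]
    boost = np.where(
        in_push[None, :] ^ style_interactive[:, None], _OUT_STYLE_DAMP, _IN_STYLE_BOOST
    )
    sa_mat = rng_msgs.random((total, len(acts))) < prevalence[None, :] * boost
    empty = ~sa_mat.any(axis=1)
    if empty.any():
        push_p = np.where(in_push, prevalence, 0.0)
        inter_p = np.where(~in_push, prevalence, 0.0)
        for i in np.where(empty)[0]:
            p = inter_p if style_interactive[i] else push_p
            sa_mat[i, rng_msgs.choice(len(acts), p=p / p.sum())] = True
    sa_sets = [frozenset(acts[j] for j in np.where(row)[0]) for row in sa_mat]

    messages = [
        MessageRecord(
            message_id=f"m{i:06d}",
            user_id=users[user_of_msg[i]],
            topic_id=f"t{msg_topics[i]:05d}",
            year=int(msg_years[i]),
            themes=theme_sets[i],
            speech_acts=sa_sets[i],
        )
        for i in range(total)
    ]
    message_counts = pd.Series(counts, index=users, dtype=int, name="engagement")
    return SyntheticCorpus(
        messages=messages,
        personas=personas,
        message_counts=message_counts,
        config=cfg,
    )


@dataclasses.dataclass
class RecoveryInstance:
    """One exact-ground-truth instance of the autocorrelation model."""

    affiliation: AffiliationMatrix
    coaff: CoaffiliationMatrix
    weight: WeightMatrix
    X: pd.DataFrame
    D: np.ndarray
    y: np.ndarray
    truth: dict


def _persona_design(
    cfg: GeneratorConfig, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Binary persona covariates drawn from the configured marginals.

    Encodes each axis as one column: any medication (oral / injectable /
    both), pre-existing diagnosis, and lifestyle change — with
    no-information levels coded 0.
    """
    m = cfg.persona_marginals
    p_med = sum(
        m["medication"].get(k, 0.0)
        for k in (
            MedicationStatus.ORAL_ONLY,
            MedicationStatus.INJECTABLE_ONLY,
            MedicationStatus.BOTH,
        )
    )
    p_dx = m["diagnosis"].get(DiagnosisStatus.PRE_EXISTING, 0.0)
    p_ls = m["lifestyle"].get(LifestyleStatus.YES, 0.0)
    return pd.DataFrame(
        {
            "intercept": np.ones(n),
            "medication": (rng.random(n) < p_med).astype(float),
            "diagnosis": (rng.random(n) < p_dx).astype(float),
            "lifestyle": (rng.random(n) < p_ls).astype(float),
        }
    )


def generate_recovery_instance(
    config: GeneratorConfig,
    theme: Theme = Theme.SOCIAL_SUPPORT,
    sa_subset=None,
    rho: Optional[float] = None,
    max_attempts: int = 10,
) -> RecoveryInstance:
    """Draw one model instance with exact ground truth.

    The binary affiliation matrix is i.i.d. Bernoulli(``affiliation_density``)
    per (user, act); C, W, D follow by the pipeline operations; X is drawn
    from the persona marginals; y from the forward model.  A degenerate draw
    where every user is an isolate is retried; after ``max_attempts``
    failures a :class:`ConfigError` carries the diagnostics.
    """
    cfg = config.validate()
    ss = np.random.SeedSequence(cfg.seed).spawn(3)
    rng_net = np.random.default_rng(ss[0])
    rng_x = np.random.default_rng(ss[1])
    rng_eps = np.random.default_rng(ss[2])

    acts = speech_act_order(sa_subset)
    n, k = cfg.n_users, len(acts)
    users = [f"u{i:04d}" for i in range(n)]
    truth_rho = cfg.nam_truth.rho if rho is None else rho

    for attempt in range(1, max_attempts + 1):
        A = (rng_net.random((n, k)) < cfg.affiliation_density).astype(int)
        aff = AffiliationMatrix(
            theme=theme, users=users, speech_acts=acts, counts=A, binary=A,
            threshold=1.0,
        )
        coaff = coaffiliation(aff)
        if not coaff.isolates().all():
            break
    else:
        raise ConfigError(
            f"degenerate affiliation network: all {n} users isolated in every "
            f"one of {max_attempts} attempts (density={cfg.affiliation_density})"
        )

    weight = row_normalize(coaff)
    X = _persona_design(cfg, n, rng_x)
    D = coaff.D.astype(float)
    y = simulate_nam(
        weight, X.to_numpy(), D,
        rho=truth_rho, beta=cfg.nam_truth.beta, gamma=cfg.nam_truth.gamma,
        sigma=cfg.nam_truth.sigma, seed=rng_eps,
    )
    truth = {
        "rho": truth_rho,
        "beta": list(cfg.nam_truth.beta),
        "gamma": cfg.nam_truth.gamma,
        "sigma": cfg.nam_truth.sigma,
        "density": cfg.affiliation_density,
        "n": n,
        "k": k,
        "seed": cfg.seed,
        "attempts": attempt,
    }
    return RecoveryInstance(
        affiliation=aff, coaff=coaff, weight=weight, X=X, D=D, y=y, truth=truth
    )


STYLE_SUBSETS = {"push_in": PUSH_IN, "interactive_turn_taking": INTERACTIVE}


def generate_sign_pattern_suite(
    seed: int,
    rho_interactive: float = 0.3,
    rho_push: float = -0.3,
    **overrides,
) -> dict[tuple[Theme, str], RecoveryInstance]:
    """Ada-like suite of 12 theme-by-style instances with signed truth.

    Interactive turn-taking networks are generated with positive network
    autocorrelation and push-in networks with negative autocorrelation; per
    theme the user count follows the published per-theme network sizes.
    Used to check that fitting reproduces the qualitative sign pattern.
    """
    suite: dict[tuple[Theme, str], RecoveryInstance] = {}
    ss = np.random.SeedSequence(seed).spawn(len(Theme) * len(STYLE_SUBSETS))
    i = 0
    for theme in Theme:
        for style, subset in STYLE_SUBSETS.items():
            sub_seed = int(ss[i].generate_state(1)[0] % (2**31))
            i += 1
            cfg = GeneratorConfig(
                seed=sub_seed, n_users=reference.THEME_USERS[theme], **overrides
            )
            rho = rho_interactive if style == "interactive_turn_taking" else rho_push
            suite[(theme, style)] = generate_recovery_instance(
                cfg, theme=theme, sa_subset=subset, rho=rho
            )
    return suite
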