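"""The neuropsychological test battery and its domain structure.

Fourteen tests grouped into six cognitive domains.  ``higher_is_better``
records the direction of each raw score: completion times, error counts,
omissions and time ratios worsen as they increase and are sign-flipped at
z-scoring so that every derived score is higher-is-better.

Mood/behaviour scales (BDI-II, PDQ-39 emotional well-being, OCI) are carried
as covariates only and never enter a cognitive score.
"""

from __future__ import annotations

import pandas as pd

DOMAINS = (
    "attention",
    "executive",
    "fluency",
    "long_term_memory",
    "working_memory",
    "visuospatial",
)

# test name -> (domain, higher_is_better, plausible normative mean, sd)
BATTERY: dict[str, tuple[str, bool, float, float]] = {
    # attention
    "stroop_color_naming_time": ("attention", False, 52.0, 9.0),
    "tmt_a_time": ("attention", False, 35.0, 11.0),
    "digit_span_backward": ("attention", True, 7.0, 2.0),
    # executive functions
    "tmt_b_to_a_ratio": ("executive", False, 2.3, 0.6),
    "stroop_interference_ratio": ("executive", False, 1.8, 0.4),
    "wcst_errors": ("executive", False, 14.0, 8.0),
    # fluency
    "phonemic_fluency": ("fluency", True, 15.0, 4.5),
    "semantic_fluency": ("fluency", True, 22.0, 5.5),
    # long-term memory
    "verbal_learning_delayed_recall": ("long_term_memory", True, 10.0, 2.8),
    "verbal_learning_discrimination": ("long_term_memory", True, 13.0, 1.8),
    # working memory ("divided attention: omissions" sits here by battery
    # convention, despite the name)
    "corsi_blocks_forward": ("working_memory", True, 8.5, 1.7),
    "divided_attention_omissions": ("working_memory", False, 2.0, 1.5),
    # visual-spatial functions
    "block_design": ("visuospatial", True, 32.0, 9.0),
    "rey_figure_copy": ("visuospatial", True, 33.0, 3.0),
}

TESTS: tuple[str, ...] = tuple(BATTERY)

MOOD_SCALES = ("bdi2", "pdq39_emotional_wellbeing", "oci")


def domain_of(test: str) -> str:
    return BATTERY[test][0]


def tests_in_domain(domain: str) -> list[str]:
    if domain not in DOMAINS:
        raise KeyError(f"unknown domain {domain!r}")
    return [t for t, (d, *_rest) in BATTERY.items() if d == domain]


def battery_table() -> pd.DataFrame:
    """The built-in battery as a DataFrame (test, domain, direction)."""
    return pd.DataFrame(
        [(t, d, hib) for t, (d, hib, _m, _s) in BATTERY.items()],
        columns=["test", "domain", "higher_is_better"],
    )
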