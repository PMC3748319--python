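"""Shared sampler of valid companion-cell profiles for property checks."""

from __future__ import annotations

import numpy as np

from phloemkey import (
    Branching,
    CCProfile,
    CWIMorphology,
    Evidence,
    Grade,
    Plastid,
    Tristate,
)
from phloemkey.cc import _hard_violations

_DOMAINS = {
    "pf_grade": list(Grade),
    "pd_branching": list(Branching),
    "cwi_grade": list(Grade),
    "cwi_morphology": list(CWIMorphology),
    "plastid": list(Plastid),
    "starch_in_leucoplasts": list(Tristate),
    "rfo_evidence": list(Evidence),
}


def sample_valid_profiles(rng: np.random.Generator, n: int) -> list[CCProfile]:
    out = []
    while len(out) < n:
        kwargs = {f: dom[rng.integers(0, len(dom))]
                  for f, dom in _DOMAINS.items()}
        profile = CCProfile(**kwargs)
        if not _hard_violations(profile):
            out.append(profile)
    return out
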