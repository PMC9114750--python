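import math

import pytest

from snpmeta import EffectEstimate, load_example_roster
from snpmeta.models import Z_975


def make_effect(log_or: float, var: float, study_id: str = "") -> EffectEstimate:
    """Build an EffectEstimate from (y, v) with a consistent 95% CI."""
    half = Z_975 * math.sqrt(var)
    return EffectEstimate(
        log_or=log_or, var=var, odds_ratio=math.exp(log_or),
        ci_low=math.exp(log_or - half), ci_high=math.exp(log_or + half),
        study_id=study_id or f"s_{log_or:+.3f}_{var:.4f}",
    )


@pytest.fixture(scope="session")
def roster():
    """The packaged 87-study roster."""
    return load_example_roster()
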