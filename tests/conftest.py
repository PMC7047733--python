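import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import ivtflow as iv

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref_design() -> iv.Design:
    """The packaged 25-run reference experiment with responses."""
    return iv.reference_design()


@pytest.fixture(scope="session")
def ref_anova(ref_design) -> iv.AnovaTable:
    return iv.anova_main_effects(ref_design)


def glm_anova_oracle(design: iv.Design) -> pd.DataFrame:
    """Independent general-linear-model ANOVA via statsmodels OLS.

    Fits delta_p ~ C(f1) + C(f2) + C(f3) and returns the anova_lm table;
    used only as a cross-check against the balanced closed form.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    frame = design.runs.copy()
    frame["y"] = design.responses
    names = [f.name for f in design.factors]
    model = ols(
        "y ~ " + " + ".join(f"C({n})" for n in names), data=frame
    ).fit()
    return sm.stats.anova_lm(model, typ=1)


def random_balanced_design(rng: np.random.Generator) -> iv.Design:
    """A balanced L25 design with random level values and responses."""
    levels = {
        name: tuple(np.sort(rng.uniform(0, 100, size=5)))
        for name in ("d_sa_mm", "a_lt_deg", "r_tt_mm")
    }
    design = iv.construct_balanced_design(levels)
    return design.with_responses(rng.normal(5.0, 2.0, size=25))
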