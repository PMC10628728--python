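import numpy as np
import pandas as pd
import pytest

from gsenspy.prs import score_prs
from gsenspy.simulate import (
    simulate_effect_sizes,
    simulate_genotypes,
    simulate_gwas_sumstats,
    simulate_phenotypes,
    standardized_outcome_h2,
    true_confounding_proportion,
)


def simulate_analysis_frame(
    seed: int,
    n: int = 2500,
    m: int = 1200,
    h2x: float = 0.25,
    h2y: float = 0.25,
    rg: float = 0.5,
    b_xy: float = 0.125,
    n_gwas: int = 20000,
):
    """Cohort -> (Sx, Sy, X, Y) frame plus the generative ground truth.

    Covariate effects are switched off so the four columns can feed the
    correlation matrix directly; the returned truth dict carries the
    heritabilities on the standardized-outcome scale, which is what a
    variance-component estimator (and hence the SEM) sees.
    """
    G = simulate_genotypes(n, m, (0.05, 0.5), seed)
    eff = simulate_effect_sizes(m, h2x, h2y, rg, G.allele_freqs, seed)
    cohort = simulate_phenotypes(G, eff, b_xy, covariate_effects={}, seed=seed)
    ss_x = simulate_gwas_sumstats(eff, G.allele_freqs, n_gwas, "x", seed)
    ss_y = simulate_gwas_sumstats(eff, G.allele_freqs, n_gwas, "y", seed + 1)
    frame = pd.DataFrame(
        {
            "Sx": score_prs(G, ss_x).scores,
            "Sy": score_prs(G, ss_y).scores,
            "X": cohort.data["exposure"].to_numpy(),
            "Y": cohort.data["outcome_att"].to_numpy(),
        }
    )
    truth = {
        "h2x": h2x,
        "h2y_std": standardized_outcome_h2(h2x, h2y, rg, b_xy),
        "pct": 100.0 * true_confounding_proportion(h2x, h2y, rg, b_xy),
        "b_xy": b_xy,
        "rg": rg,
    }
    return frame, truth


@pytest.fixture(scope="session")
def analysis_frame():
    """One medium cohort with 50% true genetic confounding, reused across tests."""
    return simulate_analysis_frame(seed=7)
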