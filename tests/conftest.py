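"""Shared fixtures: small generating models with known truth."""
import numpy as np
import pytest

from twinpath import GeneratingModel, PhenotypeCodebook, build_ipm_spec, threshold_from_prevalence

SIZES_2K = {"MZM": 2000, "MZF": 2000, "DZM": 2000, "DZF": 2000}


def ipm_generator(codebook, decomposition, prevalences, sizes, completeness=1.0):
    """GeneratingModel from per-phenotype (gen_a, gen_e, spec_a, spec_c) shares."""
    p = len(codebook)
    ga = np.zeros((p, 1))
    ge = np.zeros((p, 1))
    sa = np.zeros(p)
    sc = np.zeros(p)
    se = np.zeros(p)
    for j, name in enumerate(codebook.names):
        a, e, va, vc = decomposition[name]
        ga[j, 0] = np.sqrt(a)
        ge[j, 0] = np.sqrt(e)
        sa[j] = np.sqrt(va)
        sc[j] = np.sqrt(vc)
        se[j] = np.sqrt(1.0 - a - e - va - vc)
    tau = np.array([threshold_from_prevalence(prevalences[n]) for n in codebook.names])
    return GeneratingModel(codebook, ga, np.zeros((p, 1)), ge, sa, sc, se, tau,
                           dict(sizes), completeness=completeness)


@pytest.fixture(scope="session")
def codebook5():
    return PhenotypeCodebook(
        ["pom", "sedatives_rx", "heroin", "cannabis", "cocaine"],
        class_tags=["prescription", "prescription", "illicit", "illicit", "illicit"])


@pytest.fixture(scope="session")
def shrunken_truth():
    """5-phenotype reduced-pathway truth: one general a, one general e,
    specific a on the two prescription phenotypes only."""
    decomposition = {
        "pom": (0.14, 0.41, 0.39, 0.0),
        "sedatives_rx": (0.30, 0.35, 0.25, 0.0),
        "heroin": (0.64, 0.15, 0.0, 0.0),
        "cannabis": (0.50, 0.20, 0.0, 0.0),
        "cocaine": (0.75, 0.12, 0.0, 0.0),
    }
    prevalences = {"pom": 0.0779, "sedatives_rx": 0.0894, "heroin": 0.0131,
                   "cannabis": 0.6181, "cocaine": 0.1196}
    return decomposition, prevalences


@pytest.fixture(scope="session")
def shrunken_generator(codebook5, shrunken_truth):
    decomposition, prevalences = shrunken_truth
    return ipm_generator(codebook5, decomposition, prevalences, SIZES_2K)


@pytest.fixture(scope="session")
def shrunken_spec(codebook5):
    drops = [f"as:{n}" for n in codebook5.names if n not in ("pom", "sedatives_rx")]
    drops += [f"cs:{n}" for n in codebook5.names]
    return build_ipm_spec(codebook5, 1, 0, 1, drops=drops)


@pytest.fixture(scope="session")
def codebook3():
    return PhenotypeCodebook(["pom", "cannabis", "cocaine"],
                             class_tags=["prescription", "illicit", "illicit"])


@pytest.fixture(scope="session")
def calib3_generator(codebook3):
    """Correctly specified 3-phenotype truth with true-zero directions left
    free in the fitted spec (cannabis general-e loading and specific-a)."""
    decomposition = {
        "pom": (0.14, 0.41, 0.39, 0.0),
        "cannabis": (0.50, 0.0, 0.0, 0.0),
        "cocaine": (0.75, 0.12, 0.0, 0.0),
    }
    prevalences = {"pom": 0.0779, "cannabis": 0.6181, "cocaine": 0.1196}
    return ipm_generator(codebook3, decomposition, prevalences, SIZES_2K)


@pytest.fixture(scope="session")
def calib3_spec(codebook3):
    return build_ipm_spec(codebook3, 1, 0, 1,
                          drops=["as:cocaine"] + [f"cs:{n}" for n in codebook3.names])
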