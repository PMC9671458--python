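import numpy as np
import pytest

from patgwas import CovarianceModel
from patgwas.simulate import synthetic_trait_panel


@pytest.fixture(scope="session")
def panel4():
    """Synthetic four-trait panel (names, n, n_shared, rho_e, sigma_h2)."""
    return synthetic_trait_panel()


@pytest.fixture(scope="session")
def model4(panel4):
    """Four-trait model under the fully polygenic scaling (M = 1.5M)."""
    names, n_vec, n_shared, rho_e, sigma_h2 = panel4
    return CovarianceModel(
        n=n_vec,
        rho_e=rho_e,
        sigma_g=sigma_h2 / 1_500_000,
        n_shared=n_shared,
        trait_names=names,
    )


@pytest.fixture(scope="session")
def model4_strong(panel4):
    """Same panel with heritability spread over 20k causal variants, giving
    per-variant effects large enough that configurations are distinguishable."""
    names, n_vec, n_shared, rho_e, sigma_h2 = panel4
    return CovarianceModel(
        n=n_vec,
        rho_e=rho_e,
        sigma_g=sigma_h2 / 20_000,
        n_shared=n_shared,
        trait_names=names,
    )


@pytest.fixture(scope="session")
def model1():
    """Single-trait model matching the two-trait rejection-region design."""
    return CovarianceModel(
        n=np.array([25_000]), rho_e=np.eye(1), sigma_g=np.array([[4.9e-5]])
    )


def mvn_logpdf_dense(S, sigma):
    """Independent oracle: naive inverse + determinant density formula."""
    S = np.atleast_2d(np.asarray(S, dtype=float))
    sigma = np.asarray(sigma, dtype=float)
    T = sigma.shape[0]
    inv = np.linalg.inv(sigma)
    sign, logdet = np.linalg.slogdet(sigma)
    assert sign > 0
    quad = np.einsum("ij,jk,ik->i", S, inv, S)
    out = -0.5 * (T * np.log(2 * np.pi) + logdet + quad)
    return out if out.shape[0] > 1 else float(out[0])
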