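import pytest

from silacmrm import chromsim, frataxin

# The printed reference panel values: per (sequence, label): precursor
# charge, precursor m/z, and the three product ions with their m/z. These
# are the published 3-decimal values; computed values must match +/-0.005.
PRINTED_PANEL = {
    ("SGTLGHPGSLDDTTYER", "light"): (
        3, 602.615, [("y14^2", 780.868), ("y5^1", 669.320), ("y3^1", 467.225)]),
    ("SGTLGHPGSLDETTYER", "light"): (
        3, 607.287, [("y14^2", 787.876), ("y5^1", 669.320), ("y3^1", 467.225)]),
    ("SGTLGHPGSLDETTYER", "heavy"): (
        3, 611.300, [("y14^2", 793.896), ("y5^1", 669.320), ("y4^1", 568.273)]),
    ("QIWLSSPSSGPKR", "light"): (
        2, 721.891, [("y10^1", 1015.553), ("y9^1", 902.469), ("y8^1", 815.437)]),
    ("QIWLSSPSSGPKR", "heavy"): (
        2, 724.901, [("y10^1", 1021.573), ("y9^1", 902.469), ("y8^1", 815.437)]),
    ("LGGDLGTYVINK", "light"): (
        2, 625.343, [("y8^1", 907.525), ("y7^1", 794.441), ("y2^1", 261.156)]),
    ("LGGDLGTYVINK", "heavy"): (
        2, 631.363, [("y8^1", 913.545), ("y7^1", 794.441), ("y2^1", 261.156)]),
    ("LDLSSLAYSGK", "light"): (
        2, 577.309, [("y8^1", 812.415), ("y6^1", 638.351), ("y5^1", 525.267)]),
    ("LDLSSLAYSGK", "heavy"): (
        2, 586.339, [("y8^1", 818.435), ("y6^1", 644.371), ("y5^1", 525.267)]),
    ("NWVYSHDGVSLHELLGAELTK", "light"): (
        4, 592.804, [("y19^3", 690.029), ("y8^1", 844.514), ("y7^1", 731.430)]),
    ("NWVYSHDGVSLHELLAAELTK", "light"): (
        4, 596.308, [("y19^3", 694.700), ("y8^1", 858.530), ("y7^1", 745.445)]),
    ("NWVYSHDGVSLHELLAAELTK", "heavy"): (
        4, 602.328, [("y19^3", 702.727), ("y8^1", 876.590), ("y7^1", 757.486)]),
}

MZ_TOL = 0.005


@pytest.fixture(scope="session")
def mature_pair():
    return frataxin.mature_pair()


@pytest.fixture(scope="session")
def panel():
    return frataxin.reference_panel()


@pytest.fixture
def noiseless_config():
    """Simulation with every stochastic term switched off."""
    return chromsim.SimulationConfig(
        noise_cv=0.0,
        baseline_level=0.0,
        baseline_noise_sd=0.0,
        rt_jitter_sd=0.0,
        seed=11,
    )
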