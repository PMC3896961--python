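import pytest
from hypothesis import HealthCheck, settings

import tripletwd as tw

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

#: published pairwise weight-deviation values for the 11-species beta-globin
#: benchmark, frozen here independently of the package's bundled copy so the
#: tests do not trust the code under test for their expectations.
PUBLISHED_WD = {
    ("Human", "Chimpanzee"): 5.2500,
    ("Human", "Gorilla"): 4.3359,
    ("Human", "Black_lemur"): 8.5891,
    ("Human", "Norway_rat"): 10.670,
    ("Human", "House_mouse"): 9.7047,
    ("Human", "Goat"): 8.2219,
    ("Human", "Bovine"): 8.1438,
    ("Human", "Rabbit"): 7.8281,
    ("Human", "Opossum"): 15.6078,
    ("Human", "Gallus"): 16.7109,
    ("Chimpanzee", "Gorilla"): 1.1266,
    ("Chimpanzee", "Black_lemur"): 8.0297,
    ("Chimpanzee", "Norway_rat"): 10.645,
    ("Chimpanzee", "House_mouse"): 9.6016,
    ("Chimpanzee", "Goat"): 8.4375,
    ("Chimpanzee", "Bovine"): 9.3219,
    ("Chimpanzee", "Rabbit"): 9.6000,
    ("Chimpanzee", "Opossum"): 14.2578,
    ("Chimpanzee", "Gallus"): 15.8734,
    ("Gorilla", "Black_lemur"): 7.8688,
    ("Gorilla", "Norway_rat"): 9.9625,
    ("Gorilla", "House_mouse"): 8.6063,
    ("Gorilla", "Goat"): 7.6734,
    ("Gorilla", "Bovine"): 8.5578,
    ("Gorilla", "Rabbit"): 8.5547,
    ("Gorilla", "Opossum"): 13.9719,
    ("Gorilla", "Gallus"): 14.8781,
    ("Black_lemur", "Norway_rat"): 8.7219,
    ("Black_lemur", "House_mouse"): 9.5500,
    ("Black_lemur", "Goat"): 7.1328,
    ("Black_lemur", "Bovine"): 9.3891,
    ("Black_lemur", "Rabbit"): 5.6891,
    ("Black_lemur", "Opossum"): 12.9281,
    ("Black_lemur", "Gallus"): 15.2000,
    ("Norway_rat", "House_mouse"): 6.0750,
    ("Norway_rat", "Goat"): 7.0484,
    ("Norway_rat", "Bovine"): 9.3641,
    ("Norway_rat", "Rabbit"): 9.6578,
    ("Norway_rat", "Opossum"): 13.5906,
    ("Norway_rat", "Gallus"): 14.1219,
    ("House_mouse", "Goat"): 9.4953,
    ("House_mouse", "Bovine"): 9.2641,
    ("House_mouse", "Rabbit"): 10.7984,
    ("House_mouse", "Opossum"): 12.3406,
    ("House_mouse", "Gallus"): 12.3688,
    ("Goat", "Bovine"): 5.2625,
    ("Goat", "Rabbit"): 8.7219,
    ("Goat", "Opossum"): 11.9703,
    ("Goat", "Gallus"): 14.5359,
    ("Bovine", "Rabbit"): 9.2906,
    ("Bovine", "Opossum"): 12.5922,
    ("Bovine", "Gallus"): 15.0234,
    ("Rabbit", "Opossum"): 14.8984,
    ("Rabbit", "Gallus"): 15.6953,
    ("Opossum", "Gallus"): 14.2750,
}


@pytest.fixture(scope="session")
def table():
    return tw.build_weight_table()


@pytest.fixture(scope="session")
def beta_records():
    return tw.load_beta_globin()


@pytest.fixture(scope="session")
def beta_matrix(beta_records, table):
    return tw.pairwise_matrix(beta_records, table)
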