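import pandas as pd
import pytest

from wolfalps.classification import classify_signs
from wolfalps.synthetic import SimulationConfig, generate_signs, simulate_population


def make_sign(sign_id="S1", date="2016-01-15", x=100.0, y=100.0, country="IT",
              evidence_type="dna_sample", **attrs):
    """One signs-table row; attributes absent unless given."""
    return {"sign_id": sign_id, "date": date, "x": x, "y": y,
            "country": country, "evidence_type": evidence_type, **attrs}


def signs_frame(rows):
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def reference_run():
    """One synthetic dataset shared across tests (fixed reference seed)."""
    cfg = SimulationConfig(seed=42, n_years=8, initial_units=4)
    truth = simulate_population(cfg)
    signs, links = generate_signs(truth, cfg)
    classified = classify_signs(signs)
    return {"config": cfg, "truth": truth, "signs": signs,
            "links": links, "classified": classified}
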