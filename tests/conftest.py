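import numpy as np
import pytest

from anchorlink.irt_core import generate_abilities, generate_item_bank, simulate_responses


@pytest.fixture(scope="session")
def small_bank():
    return generate_item_bank(tss=20, n_anchor=3, c=0.0, rng_seed=42)


@pytest.fixture(scope="session")
def calibrated_form():
    """A single fitted 2PL form reused by several tests (n=500, 20 items)."""
    from anchorlink.calibration import fit_irt

    bank = generate_item_bank(tss=20, n_anchor=3, c=0.0, rng_seed=7)
    items = bank.form_items(2)
    abilities = generate_abilities(500, 0.0, 1.0, form_index=2, rng_seed=8)
    responses = simulate_responses(abilities, items, rng_seed=9)
    result = fit_irt(responses, model="2PL")
    return {"bank": bank, "items": items, "abilities": abilities,
            "responses": responses, "result": result}
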