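"""Shared fixtures: synthetic fields generated once per session."""

import numpy as np
import pytest

from centroquant import SynthConfig, control_kappa, generate_field, render_stack


@pytest.fixture(scope="session")
def control_field():
    """Ground-truth field, control angular preset, default geometry."""
    cfg = SynthConfig(n_cells=80, kappa=control_kappa(), seed=101)
    return generate_field(cfg)


@pytest.fixture(scope="session")
def rendered_bundle():
    """A rendered wound field plus its ground truth and stack origin.

    Shallow two-strip geometry so a good share of cells sit in the first
    row next to the wound.
    """
    cfg = SynthConfig(n_cells=40, kappa=control_kappa(), seed=5,
                      spots_per_cell=6, centrosome_spot_fraction=0.3,
                      field_size_um=(260.0, 25.0))
    field = generate_field(cfg)
    stack = render_stack(field)
    return field, stack, np.array(stack.origin_um)
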