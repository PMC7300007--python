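import pandas as pd
import pytest

from prmpanel import SyntheticConfig


def make_transition_rows(
    sample="S1",
    protein="PD-L1",
    peptide="PDLSIGPEPK",
    heavy_areas=(50.0, 40.0, 30.0, 20.0, 10.0),
    ratio=0.4,
    light_ppm=None,
    light_rt=None,
    rt=20.0,
):
    """Long-format light/heavy transitions for one peptide, hand-specified.

    Light areas default to ``ratio * heavy``; per-fragment light mass errors
    and retention times can be overridden to corrupt individual transitions.
    """
    fragments = [f"y{3 + i:02d}" for i in range(len(heavy_areas))]
    light_ppm = light_ppm or [0.0] * len(fragments)
    light_rt = light_rt or [rt] * len(fragments)
    rows = []
    for i, frag in enumerate(fragments):
        rows.append((sample, protein, peptide, frag, "heavy", heavy_areas[i], 0.0, rt))
        rows.append(
            (sample, protein, peptide, frag, "light",
             ratio * heavy_areas[i], light_ppm[i], light_rt[i])
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "protein_id", "peptide_seq", "fragment_id",
            "label", "area", "mass_error_ppm", "rt_apex",
        ],
    )


@pytest.fixture
def clean_peptide():
    """Five concordant transitions, ratio 0.4 -> 0.2 fmol/ug."""
    return make_transition_rows()


@pytest.fixture
def two_corrupted_peptide():
    """Five transitions, one off-mass (6 ppm) and one not co-eluting."""
    return make_transition_rows(
        light_ppm=[1.0, -2.0, 0.0, 6.0, 0.0],
        light_rt=[20.0, 20.0, 20.0, 20.0, 20.5],
    )


@pytest.fixture
def single_survivor_peptide():
    """Only one light transition passes the mass-accuracy filter."""
    return make_transition_rows(light_ppm=[1.0, 7.0, -7.0, 8.0, -9.0])


@pytest.fixture
def noise_free_config():
    return SyntheticConfig(
        n_samples=8,
        area_cv=0.0,
        ppm_sd=0.0,
        interference_rate=0.0,
        seed=3,
    )
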