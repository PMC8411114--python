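import numpy as np
import pandas as pd
import pytest

from phoscale import io as pio


@pytest.fixture
def balanced_labels():
    """Arm / biological-replicate labels of one complete 4x3x2 pair matrix."""
    arm = np.array(["treated"] * 12 + ["control"] * 12)
    bio = np.tile(np.repeat(np.arange(1, 5), 3), 2)
    return arm, bio


@pytest.fixture
def pair_design():
    """Design covering one timepoint: bic + control, 4 bio x 3 tech."""
    design = []
    for trt in ("bic", "control"):
        for b in range(1, 5):
            for t in range(1, 4):
                design.append(
                    pio.SampleDesign(
                        sample_id=f"{trt}_5min_b{b}_t{t}",
                        treatment=trt,
                        timepoint="5min",
                        bio_rep=b,
                        tech_rep=t,
                    )
                )
    return design


@pytest.fixture
def full_design():
    return pio.default_design()


def make_site_file(tmp_path, rows, sample_ids=("S1",), name="sites.tsv"):
    """Write a minimal MaxQuant-dialect phosphosite table.

    ``rows`` are dicts that may override any column; intensity defaults to 0
    (missing) for every (sample, slot) column not given.
    """
    columns = list(pio.SITE_COLUMNS) + [
        f"Intensity {sid}___{k}" for sid in sample_ids for k in (1, 2, 3)
    ]
    defaults = {
        "Proteins": "P1",
        "Gene names": "Gene1",
        "Position": 10,
        "Amino acid": "S",
        "Localization prob": 0.99,
        "Reverse": "",
        "Potential contaminant": "",
    }
    data = []
    for row in rows:
        full = {c: 0 for c in columns}
        full.update(defaults)
        full.update(row)
        data.append(full)
    path = tmp_path / name
    pd.DataFrame(data, columns=columns).to_csv(path, sep="\t", index=False)
    return path


def site_design(sample_ids=("S1",)):
    """One-timepoint design whose sample ids match make_site_file."""
    out = []
    for i, sid in enumerate(sample_ids):
        out.append(
            pio.SampleDesign(
                sample_id=sid,
                treatment="bic" if i % 2 == 0 else "control",
                timepoint="5min",
                bio_rep=i // 3 % 4 + 1,
                tech_rep=i % 3 + 1,
            )
        )
    return out
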