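import numpy as np
import pandas as pd
import pytest

from steppanel.panel_io import CountMatrix, PanelDefinition


@pytest.fixture
def small_panel() -> PanelDefinition:
    """Minimal panel: 6 endogenous (incl. regulators), 3 HK, 3 POS, 2 NEG."""
    return PanelDefinition.from_records(
        [
            ("ASCL1", "Endogenous"),
            ("NEUROD1", "Endogenous"),
            ("POU2F3", "Endogenous"),
            ("YAP1", "Endogenous"),
            ("DLL3", "Endogenous"),
            ("GENE6", "Endogenous"),
            ("ACTB", "Housekeeping"),
            ("GAPDH", "Housekeeping"),
            ("TBP", "Housekeeping"),
            ("POS_A", "Positive", 128.0),
            ("POS_B", "Positive", 32.0),
            ("POS_C", "Positive", 8.0),
            ("NEG_A", "Negative"),
            ("NEG_B", "Negative"),
        ]
    )


def make_sheet(sample_ids, batch_ids, references, **extra):
    rows = []
    for i, sid in enumerate(sample_ids):
        rows.append(
            dict(
                sample_id=sid,
                batch_id=batch_ids[i],
                patient_id=extra.get("patient_ids", [""] * len(sample_ids))[i],
                tissue_site=extra.get("tissue_sites", [""] * len(sample_ids))[i],
                histology=extra.get("histologies", ["SCLC"] * len(sample_ids))[i],
                is_reference=references[i],
                tumor_pct=np.nan,
            )
        )
    return pd.DataFrame(rows).set_index("sample_id")


@pytest.fixture
def toy_cohort(small_panel) -> CountMatrix:
    """Two samples + one reference in one batch, hand-sized counts."""
    counts = pd.DataFrame(
        {
            "REF": [100, 100, 100, 100, 100, 100, 200, 200, 200, 640, 160, 40, 4, 6],
            "S1": [400, 100, 50, 25, 300, 100, 200, 200, 200, 640, 160, 40, 5, 5],
            "S2": [100, 300, 100, 50, 100, 100, 200, 200, 200, 640, 160, 40, 6, 4],
        },
        index=small_panel.genes,
    )
    sheet = make_sheet(["REF", "S1", "S2"], ["B1"] * 3, [True, False, False])
    return CountMatrix(counts=counts, panel=small_panel, samples=sheet)
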