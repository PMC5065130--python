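import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from enzevo.variant_io import ActivityRecord


def make_records(
    variant_id: str,
    parent_id: str,
    substrate: str,
    values_by_batch: dict[str, list[float]],
    od600: float | None = None,
    genotype: str = "",
    detection_limit: float | None = None,
    censor: str = "none",
    dataset: str = "test",
) -> list[ActivityRecord]:
    """Build replicate records from a {batch: [rates]} mapping."""
    records = []
    for batch, rates in values_by_batch.items():
        for i, rate in enumerate(rates):
            records.append(
                ActivityRecord(
                    variant_id=variant_id,
                    parent_id=parent_id,
                    substrate=substrate,
                    batch=batch,
                    replicate=i + 1,
                    rate=rate,
                    od600=od600,
                    detection_limit=detection_limit,
                    censor=censor,
                    genotype=genotype,
                    dataset=dataset,
                )
            )
    return records


@pytest.fixture
def records_factory():
    return make_records
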