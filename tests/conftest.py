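import numpy as np
import pytest

from metaquin.design import SequinRecord
from metaquin.simulate import generate_fixture_genomes


def make_sequins(n: int, seed: int = 0) -> list[SequinRecord]:
    """Fabricated sequin records (metadata only) for mixture-level tests."""
    rng = np.random.default_rng(seed)
    out = []
    width = max(2, len(str(n)))
    for i in range(n):
        length = int(rng.integers(1000, 10001))
        out.append(
            SequinRecord(
                id=f"MG_{i + 1:0{width}d}",
                sequence="",
                length=length,
                gc=float(rng.uniform(0.2, 0.71)),
                source_id=f"genome_{i + 1}",
                source_window=(0, length),
            )
        )
    return out


@pytest.fixture(scope="session")
def sequins86() -> list[SequinRecord]:
    return make_sequins(86, seed=42)


@pytest.fixture(scope="session")
def small_genomes() -> dict[str, str]:
    return generate_fixture_genomes(5, (15000, 25000), seed=7)
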