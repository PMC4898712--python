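import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from rrnatax import Lineage, ReferenceRecord, parse_lineage

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_taxonomy():
    """Two genera sharing a family, plus an outgroup phylum."""
    return {
        "refA": parse_lineage("Bacteria;Spirochaetes;Spirochaetia;Spirochaetales;Spirochaetaceae;Treponema"),
        "refB": parse_lineage("Bacteria;Spirochaetes;Spirochaetia;Spirochaetales;Spirochaetaceae;Borrelia"),
        "refC": parse_lineage("Bacteria;Firmicutes;Bacilli;Lactobacillales;Streptococcaceae;Streptococcus"),
    }


@pytest.fixture
def tiny_references(rng):
    """Three 400-nt references with ~15% pairwise divergence and lineages."""
    root = random_dna(rng, 400)

    def mutate(seq, rate):
        out = list(seq)
        for i in range(len(out)):
            if rng.random() < rate:
                out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
        return "".join(out)

    lineages = [
        "Bacteria;Spirochaetes;Spirochaetia;Spirochaetales;Spirochaetaceae;Treponema",
        "Bacteria;Spirochaetes;Spirochaetia;Spirochaetales;Spirochaetaceae;Borrelia",
        "Bacteria;Firmicutes;Bacilli;Lactobacillales;Streptococcaceae;Streptococcus",
    ]
    return [
        ReferenceRecord(f"ref{chr(65 + i)}", mutate(root, 0.08), parse_lineage(lin))
        for i, lin in enumerate(lineages)
    ]
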