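import numpy as np
import pytest

from duplidate.config import PipelineConfig

CODON_ALPHABET = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


def random_codon_row(rng: np.random.Generator, n_codons: int,
                     gap_frac: float = 0.05, n_frac: float = 0.02) -> str:
    """A random aligned codon row over all 64 codons plus gap and N codons."""
    out = []
    for _ in range(n_codons):
        u = rng.random()
        if u < gap_frac:
            out.append("---")
        elif u < gap_frac + n_frac:
            codon = list(CODON_ALPHABET[rng.integers(64)])
            codon[rng.integers(3)] = "N"
            out.append("".join(codon))
        else:
            out.append(CODON_ALPHABET[rng.integers(64)])
    return "".join(out)


def random_species_newick(rng: np.random.Generator, labels: list[str]) -> str:
    """Random rooted binary topology over the labels (no branch lengths)."""

    def build(names: list[str]) -> str:
        if len(names) == 1:
            return names[0]
        k = int(rng.integers(1, len(names)))
        return f"({build(names[:k])},{build(names[k:])})"

    shuffled = list(labels)
    rng.shuffle(shuffled)
    return build(shuffled) + ";"
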