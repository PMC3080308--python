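import random

import pytest

from dyadscan import SequenceSet, build_index


@pytest.fixture(scope="session")
def agct_index():
    """Index of the string whose tree groups AG..AGCTA under one locus."""
    return build_index("AGCTAGCTAAA")


@pytest.fixture(scope="session")
def interleave_index():
    """y = G at {1,7}, z = T at {3,5,9}: the interleaving configuration."""
    return build_index("GATATAGAT")


def random_sequence_set(rng: random.Random, max_n: int = 100,
                        sigma: str = "ACGT", max_records: int = 2
                        ) -> SequenceSet:
    n_rec = rng.randint(1, max_records)
    recs = []
    for _ in range(n_rec):
        n = rng.randint(3, max(3, max_n // n_rec))
        recs.append("".join(rng.choice(sigma) for _ in range(n)))
    return SequenceSet.from_strings(recs)


def random_query_words(rng: random.Random, seqs: SequenceSet,
                       max_len: int = 3) -> tuple[str, str]:
    """Two words guaranteed to occur in the set (substrings of a record)."""
    words = []
    for _ in range(2):
        _, s = seqs.records[rng.randrange(seqs.n_records)]
        i = rng.randrange(len(s))
        words.append(s[i: i + rng.randint(1, max_len)])
    return tuple(words)
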