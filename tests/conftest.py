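from __future__ import annotations

import pandas as pd
import pytest

from spliceseek import BUNDLED_SUBSTRATES, Substrate
from spliceseek.io import concat_peaklists


@pytest.fixture(scope="session")
def sub13() -> Substrate:
    return BUNDLED_SUBSTRATES["gp100_40-52"]


@pytest.fixture(scope="session")
def sub23() -> Substrate:
    return BUNDLED_SUBSTRATES["gp100_35-57"]


@pytest.fixture()
def tiny() -> Substrate:
    return Substrate("tiny", "ACDE")


def combine(peaklists: dict[float, pd.DataFrame]) -> pd.DataFrame:
    return concat_peaklists(peaklists.values())


# ---- independent brute-force oracle for product enumeration ----------------
# Pure integer loops over (i, j, k, n); deliberately shares no code with the
# package implementation.

def oracle_fragments(L: int, l_ext: int) -> list[tuple[int, int]]:
    return [
        (i, j)
        for i in range(1, L + 1)
        for j in range(i, L + 1)
        if j - i + 1 >= l_ext
    ]


def oracle_counts(L: int, l_ext: int) -> dict[str, int]:
    frags = oracle_fragments(L, l_ext)
    out = {"pcp": len(frags), "cis_normal": 0, "cis_reverse": 0, "trans": 0, "adjacent": 0}
    for (i, j) in frags:
        for (k, n) in frags:
            if k == j + 1:
                out["adjacent"] += 1
            elif k >= j + 2:
                out["cis_normal"] += 1
            elif i >= n + 1:
                out["cis_reverse"] += 1
            else:
                out["trans"] += 1
    return out
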