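"""Shared fixtures: the embedded library and a small prepared subset.

Heavy objects (library coordinates, conformer databases) are session-scoped
so the suite builds them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from blobid.config import PipelineConfig
from blobid.ligands import builtin_library
from blobid.pipeline import prepare_library

#: compact subset spanning rigid/flexible and small/large ligands
SMALL_CODES = ["SO4", "IMD", "GOL", "PYR", "CIT", "MES", "MYR", "ATP"]


@pytest.fixture(scope="session")
def library():
    return builtin_library()


@pytest.fixture(scope="session")
def fast_config():
    return PipelineConfig.fast()


@pytest.fixture(scope="session")
def small_prepared(library, fast_config):
    """(store, db) for a compact 8-ligand library, 15 conformers each."""
    mols = [m for m in library if m.code in SMALL_CODES]
    return prepare_library(mols, max_conformers=15, config=fast_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
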