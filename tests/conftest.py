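import csv

import pytest
from hypothesis import HealthCheck, settings

from fusiongrep.classify import ClassifierParams, classify_read
from fusiongrep.data import (
    load_fixture_references,
    published_reads_path,
    published_annotations_path,
)
from fusiongrep.retrieval import AnchorSpec, read_sequences, scan_reads

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def kat6a_ref():
    return load_fixture_references()[0]


@pytest.fixture(scope="session")
def crebbp_ref():
    return load_fixture_references()[1]


@pytest.fixture(scope="session")
def anchor_spec():
    return AnchorSpec()


@pytest.fixture(scope="session")
def params():
    return ClassifierParams()


@pytest.fixture(scope="session")
def published_reads():
    """The 26 packaged published junction-region reads, id -> sequence."""
    return {r.read_id: r.sequence for r in read_sequences(published_reads_path())}


@pytest.fixture(scope="session")
def published_truth():
    """Published per-read annotations, id -> row dict."""
    with open(published_annotations_path(), newline="") as fh:
        return {row["read_id"]: row for row in csv.DictReader(fh, delimiter="\t")}


@pytest.fixture(scope="session")
def published_anchored(anchor_spec):
    return list(scan_reads(read_sequences(published_reads_path()), anchor_spec))


@pytest.fixture(scope="session")
def published_classified(published_anchored, kat6a_ref, crebbp_ref, anchor_spec, params):
    return [
        classify_read(ar, [kat6a_ref], crebbp_ref, anchor_spec, params)
        for ar in published_anchored
    ]
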