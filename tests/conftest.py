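import pytest

from pvsignal.faers_io import CalendarDate, CaseRecord, DrugEntry


def make_record(primaryid="1001", caseid="100", fda="20230601", sex="unknown",
                events=(), drugs=(), event_dt=None, outcomes=(), **kwargs):
    """Terse CaseRecord builder for tests.

    ``drugs`` is a sequence of (canonical, role) or (verbatim, canonical,
    role, start_token) tuples.
    """
    from pvsignal.faers_io import parse_date

    entries = []
    for spec in drugs:
        if len(spec) == 2:
            canonical, role = spec
            entries.append(DrugEntry(canonical or "x", canonical, role, None))
        else:
            verbatim, canonical, role, start = spec
            entries.append(DrugEntry(verbatim, canonical, role,
                                     parse_date(start) if start else None))
    return CaseRecord(
        primaryid=primaryid, caseid=caseid,
        fda_dt=parse_date(fda) or CalendarDate(1900),
        sex=sex, events=set(events), drugs=entries,
        event_dt=parse_date(event_dt) if event_dt else None,
        outcomes=set(outcomes), **kwargs)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def small_dataset(tmp_path):
    """A small generated dataset on disk plus its ground truth."""
    from pvsignal.synthetic_data import paper_like_config, simulate_dataset

    config = paper_like_config(seed=11, n_reports=4000)
    path, truth = simulate_dataset(config, tmp_path / "ds")
    return path, truth, config
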