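"""End-to-end orchestration: dataset directory -> deduplicated records ->
screened signal tables, with stage counts for the audit log."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from . import synthetic_data
from .contingency import PtSocMap
from .dedup_normalize import (SynonymDictionary, deduplicate,
                              default_synonyms)
from .dpa_stats import (BcpnnPriors, ExclusionList, ScreenResult,
                        SignalCriteria, default_exclusions, screen_signals)
from .faers_io import CaseRecord, RejectedRow, assemble_records


@dataclass(slots=True)
class LoadedDataset:
    records: list[CaseRecord]
    soc_map: PtSocMap | None
    synonyms: SynonymDictionary
    stage_counts: dict[str, int] = field(default_factory=dict)
    rejects: list[RejectedRow] = field(default_factory=list)


def load_dataset(data_dir: str | Path,
                 synonyms: SynonymDictionary | None = None,
                 soc_map_path: str | Path | None = None,
                 delimiter: str = "$") -> LoadedDataset:
    """Parse all quarters in a directory, assemble and deduplicate.

    Stage counts record reports in, rejected rows, assembled records and
    records after deduplication.
    """
    data_dir = Path(data_dir)
    if synonyms is None:
        synonyms = default_synonyms()
    quarters = synthetic_data.load_quarters(data_dir, delimiter=delimiter)
    records, stats = assemble_records(quarters, synonyms)
    result = deduplicate(records)

    if soc_map_path is None:
        candidate = data_dir / "pt_soc.csv"
        soc_map_path = candidate if candidate.exists() else None
    soc_map = PtSocMap.from_csv(soc_map_path) if soc_map_path else None

    rejects = [r for q in quarters for r in q.rejects]
    counts = {
        "quarters": len(quarters),
        "rows_rejected": len(rejects),
        "records_assembled": len(records),
        "dropped_no_demo": stats.dropped_no_demo,
        "after_dedup": len(result.kept),
        "duplicates_removed": result.removed_count,
    }
    return LoadedDataset(records=result.kept, soc_map=soc_map,
                         synonyms=synonyms, stage_counts=counts,
                         rejects=rejects)


def run_screen(dataset: LoadedDataset, drug: str,
               exclusions: ExclusionList | None = None,
               criteria: SignalCriteria = SignalCriteria(),
               priors: BcpnnPriors = BcpnnPriors(),
               correction: bool = False) -> ScreenResult:
    """Screen one drug against the rest of the loaded dataset."""
    if dataset.soc_map is None:
        raise ValueError("dataset has no PT->SOC map; pass soc_map_path")
    if exclusions is None:
        exclusions = default_exclusions()
    targets = sorted(dataset.synonyms.canonical_names)
    if drug not in targets:
        from .dedup_normalize import UnknownDrugError
        raise UnknownDrugError(drug, targets)
    return screen_signals(dataset.records, drug, dataset.soc_map,
                          exclusions=exclusions, criteria=criteria,
                          priors=priors, correction=correction,
                          targets=targets)
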