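"""Configuration, file formats and the end-to-end pipeline driver.

Canonical on-disk formats: FASTA/FASTQ for sequences, TSV (tab-separated,
UTF-8, header row) for tables, JSON for reports and echoed configuration.
FASTA headers produced by the pipeline are pipe-delimited:
``>specimenID|trapID|family``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import community as community_mod
from . import demux_call, motu, neglect, synthio
from .errors import ConfigError, DataError

__all__ = [
    "RunConfig",
    "RunReport",
    "run_pipeline",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_tsv",
    "write_tsv",
    "read_demux_sheet",
    "write_demux_sheet",
]

log = logging.getLogger("darktaxa")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA as (header, sequence) pairs (full header line kept)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.description, str(rec.seq)))
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> int:
    seq_records = [
        SeqRecord(Seq(seq), id=header, description="") for header, seq in records
    ]
    return SeqIO.write(seq_records, str(path), "fasta")


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """Validating FASTQ reader: (id, sequence, quality) triples.

    Malformed records raise :class:`DataError` carrying the 1-based line
    number of the offending line.
    """
    out = []
    with open(path, encoding="utf-8") as handle:
        lines = handle.read().splitlines()
    if len(lines) % 4 != 0:
        raise DataError(f"{path}: truncated FASTQ (line {len(lines) + 1})")
    for i in range(0, len(lines), 4):
        header, seq, plus, qual = lines[i : i + 4]
        if not header.startswith("@"):
            raise DataError(f"{path}: line {i + 1}: header must start with '@'")
        if not plus.startswith("+"):
            raise DataError(f"{path}: line {i + 3}: separator must start with '+'")
        if len(seq) != len(qual):
            raise DataError(
                f"{path}: line {i + 4}: quality length {len(qual)} != sequence length {len(seq)}"
            )
        out.append((header[1:].split()[0], seq, qual))
    return out


def write_fastq(path: str | Path, records: Iterable[tuple[str, str]]) -> int:
    """Write (id, sequence) pairs with a constant placeholder quality."""
    n = 0
    with open(path, "w", encoding="utf-8") as handle:
        for read_id, seq in records:
            handle.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(path: str | Path, frame: pd.DataFrame, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def write_demux_sheet(path: str | Path, sheet: demux_call.DemuxSheet) -> None:
    rows = [
        {
            "specimen": specimen,
            "fwd_tag": fwd,
            "rev_tag": rev,
            "trap": sheet.traps.get(specimen, "unassigned"),
        }
        for specimen, (fwd, rev) in sorted(sheet.entries.items())
    ]
    write_tsv(path, pd.DataFrame(rows))


def read_demux_sheet(
    path: str | Path,
    primer_fwd: str,
    primer_rev: str,
    max_primer_mismatches: int = 2,
    max_tag_mismatches: int = 0,
) -> demux_call.DemuxSheet:
    frame = read_tsv(path)
    required = {"specimen", "fwd_tag", "rev_tag"}
    missing = required - set(frame.columns)
    if missing:
        raise DataError(f"{path}: demux sheet missing columns {sorted(missing)}")
    entries = {
        row.specimen: (row.fwd_tag, row.rev_tag) for row in frame.itertuples()
    }
    traps = (
        {row.specimen: row.trap for row in frame.itertuples()}
        if "trap" in frame.columns
        else {}
    )
    return demux_call.DemuxSheet(
        entries=entries,
        primer_fwd=primer_fwd,
        primer_rev=primer_rev,
        traps=traps,
        max_primer_mismatches=max_primer_mismatches,
        max_tag_mismatches=max_tag_mismatches,
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Every stage toggle and threshold of one pipeline run, explicit."""

    seed: int = 0
    out_dir: str = "darktaxa_run"

    # stage toggles
    simulate: bool = True
    callbarcodes: bool = True
    cluster: bool = True
    community: bool = True
    neglect: bool = True

    # community scenario
    n_traps: int = 20
    n_families: int = 10
    family_profile: tuple[float, ...] | None = None
    profile_noise_sd: float = 0.0
    species_mean: float = 10.0
    species_dispersion: float | None = None
    turnover: float = 0.9
    abundance_shape: float = 0.9
    intra_sub_max: int = 1

    # read simulation
    tag_length: int = 13
    primer_fwd: str = synthio.DEFAULT_PRIMER_FWD
    primer_rev: str = synthio.DEFAULT_PRIMER_REV
    depth_mean: float = 60.0
    depth_dispersion: float | None = None
    error_rate: float = 0.0

    # demultiplexing / calling thresholds
    max_primer_mismatches: int = 2
    max_tag_mismatches: int = 0
    min_total_reads: int = 50
    min_support: int = 10
    dominance: float = 5.0

    # quality filters
    expected_length: int = 313
    reading_frame: int = 2
    min_barcodes_per_trap: int = 100

    # clustering
    threshold: float = 0.03
    min_overlap: int = 100

    # community stats
    top_n: int = 20
    log_offset: float = 0.01
    min_specimens: int = 11
    min_samples: int = 2

    # neglect / bibliography
    s_threshold: float = 50.0
    zero_offset: float = 1.0
    biblio_intensity: float = 15.0
    biblio_author_pool: int = 10
    described_backlog_factor: float = 4.0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if path.suffix in (".toml", ".tml"):
            with open(path, "rb") as fh:
                raw = tomllib.load(fh)
        elif path.suffix in (".yaml", ".yml"):
            with open(path, encoding="utf-8") as fh:
                raw = yaml.safe_load(fh) or {}
        else:
            raise ConfigError(f"unsupported config format: {path.suffix}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "family_profile" in raw and raw["family_profile"] is not None:
            raw["family_profile"] = tuple(raw["family_profile"])
        return cls(**raw)

    def resolved_profile(self) -> tuple[float, ...]:
        if self.family_profile is not None:
            return tuple(self.family_profile)
        # geometric-series default profile, normalised
        weights = [0.7**i for i in range(self.n_families)]
        total = sum(weights)
        return tuple(w / total for w in weights)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["family_profile"] = list(self.resolved_profile())
        return d


@dataclass
class RunReport:
    """Per-stage record counts and headline statistics of one run."""

    seed: int
    stages: dict[str, dict] = field(default_factory=dict)
    statistics: dict[str, object] = field(default_factory=dict)

    def add_stage(self, name: str, n_in: int, n_out: int, rejected: Mapping[str, int] | None = None) -> None:
        rejected = dict(rejected or {})
        n_rej = sum(rejected.values())
        if n_out + n_rej != n_in:
            raise DataError(
                f"stage {name}: counts do not reconcile ({n_out} + {n_rej} != {n_in})"
            )
        self.stages[name] = {"in": n_in, "out": n_out, "rejected": rejected}

    def to_json(self) -> str:
        return json.dumps(
            {"seed": self.seed, "stages": self.stages, "statistics": self.statistics},
            indent=2,
            sort_keys=True,
            default=_jsonable,
        )


def _jsonable(obj):
    if isinstance(obj, (pd.Series,)):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

def _check_dependencies(config: RunConfig) -> None:
    order = ["simulate", "callbarcodes", "cluster", "community"]
    enabled = [getattr(config, name) for name in order]
    for i, name in enumerate(order[1:], start=1):
        if enabled[i] and not all(enabled[:i]):
            missing = [n for n in order[:i] if not getattr(config, n)]
            raise ConfigError(
                f"stage {name!r} enabled but depends on disabled stage(s) {missing}"
            )
    if config.neglect and not (config.simulate and config.cluster):
        raise ConfigError("stage 'neglect' needs 'simulate' and 'cluster'")


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute simulate -> callbarcodes -> cluster -> community -> neglect.

    All artifacts plus the echoed configuration are written under
    ``config.out_dir``. Deterministic for a fixed seed.
    """
    _check_dependencies(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config.echo(), indent=2, sort_keys=True))
    report = RunReport(seed=config.seed)

    if not config.simulate:
        raise ConfigError("runs from pre-existing inputs must start at the CLI "
                          "subcommands; the driver currently always simulates")

    # --- simulate ---------------------------------------------------------
    scenario = synthio.CommunityScenario(
        n_traps=config.n_traps,
        n_families=config.n_families,
        family_profile=config.resolved_profile(),
        profile_noise_sd=config.profile_noise_sd,
        species_mean=config.species_mean,
        species_dispersion=config.species_dispersion,
        turnover=config.turnover,
        abundance_shape=config.abundance_shape,
        intra_sub_max=config.intra_sub_max,
        seed=config.seed,
    )
    truth = synthio.simulate_community(scenario)
    specimens = truth.specimens
    write_tsv(out / "truth_specimens.tsv", specimens)
    write_fasta(
        out / "true_barcodes.fasta",
        (
            (f"{r.specimen_id}|{r.trap}|{r.family}|{r.species}", r.sequence)
            for r in specimens.itertuples()
        ),
    )
    read_spec = synthio.ReadSimSpec(
        tag_length=config.tag_length,
        primer_fwd=config.primer_fwd,
        primer_rev=config.primer_rev,
        depth_mean=config.depth_mean,
        depth_dispersion=config.depth_dispersion,
        error_rate=config.error_rate,
        seed=config.seed + 1,
    )
    traps_by_specimen = dict(zip(specimens["specimen_id"], specimens["trap"]))
    sheet = synthio.build_demux_sheet(
        traps_by_specimen, read_spec, max_primer_mismatches=config.max_primer_mismatches
    )
    barcode_by_specimen = dict(zip(specimens["specimen_id"], specimens["sequence"]))
    reads, provenance = synthio.simulate_reads(barcode_by_specimen, sheet, read_spec)
    write_fastq(out / "reads.fastq", reads)
    write_demux_sheet(out / "demux_sheet.tsv", sheet)
    write_tsv(out / "read_provenance.tsv", provenance)
    report.add_stage("simulate", n_in=len(specimens), n_out=len(specimens))
    log.info("simulated %d specimens, %d reads", len(specimens), len(reads))

    # --- demultiplex + call ----------------------------------------------
    tagged = (demux_call.TaggedRead(read_id=i, sequence=s) for i, s in reads)
    demux = demux_call.demultiplex(tagged, sheet)
    report.add_stage(
        "demultiplex",
        n_in=demux.n_total,
        n_out=demux.n_assigned,
        rejected={"unassigned": demux.n_unassigned},
    )
    family_by_specimen = dict(zip(specimens["specimen_id"], specimens["family"]))
    called: list[demux_call.BarcodeRecord] = []
    uncalled = 0
    for specimen in sorted(demux.amplicons):
        rec = demux_call.call_barcode(
            demux.amplicons[specimen],
            min_total=config.min_total_reads,
            min_support=config.min_support,
            dominance=config.dominance,
        )
        if rec is None:
            uncalled += 1
        else:
            called.append(
                dataclasses.replace(
                    rec,
                    trap=traps_by_specimen[specimen],
                    family=family_by_specimen[specimen],
                )
            )
    report.add_stage(
        "call_barcode",
        n_in=len(demux.amplicons),
        n_out=len(called),
        rejected={"uncalled": uncalled},
    )
    kept, rejections = demux_call.filter_barcodes(
        called, expected_length=config.expected_length, reading_frame=config.reading_frame
    )
    reasons: dict[str, int] = {}
    for _, reason in rejections:
        reasons[reason] = reasons.get(reason, 0) + 1
    report.add_stage("filter_barcodes", n_in=len(called), n_out=len(kept), rejected=reasons)
    kept, dropped_traps = demux_call.filter_samples(
        kept, min_barcodes=config.min_barcodes_per_trap
    )
    report.add_stage(
        "filter_samples",
        n_in=report.stages["filter_barcodes"]["out"],
        n_out=len(kept),
        rejected={"small_trap": report.stages["filter_barcodes"]["out"] - len(kept)},
    )
    write_fasta(
        out / "barcodes.fasta",
        ((f"{r.specimen_id}|{r.trap}|{r.family}", r.sequence) for r in kept),
    )
    write_tsv(
        out / "rejections.tsv",
        pd.DataFrame(rejections, columns=["specimen_id", "reason"]),
    )
    if not kept:
        raise DataError("no barcodes survived calling and filtering")

    # --- cluster ----------------------------------------------------------
    labels = [r.specimen_id for r in kept]
    partition = motu.cluster_sequences(
        labels,
        [r.sequence for r in kept],
        threshold=config.threshold,
        min_overlap=config.min_overlap,
    )
    write_tsv(out / "motu_partition.tsv", partition.to_frame())
    trap_of = {r.specimen_id: r.trap for r in kept}
    family_of = {r.specimen_id: r.family for r in kept}
    per_trap = motu.count_motus(partition, trap_of)
    per_family = motu.count_motus(partition, family_of)
    write_tsv(out / "motus_per_trap.tsv", per_trap.rename_axis("trap").reset_index())
    write_tsv(out / "motus_per_family.tsv", per_family.rename_axis("family").reset_index())
    report.add_stage("cluster", n_in=len(kept), n_out=len(kept))
    report.statistics["n_motus"] = partition.n_clusters
    report.statistics["motus_per_trap"] = per_trap

    # --- community --------------------------------------------------------
    barcode_frame = pd.DataFrame(
        {
            "specimen_id": labels,
            "trap": [r.trap for r in kept],
            "family": [r.family for r in kept],
            "cluster": [partition.assignment[lab] for lab in labels],
        }
    )
    counts = (
        barcode_frame.groupby(["trap", "family"])["cluster"]
        .nunique()
        .unstack(fill_value=0)
    )
    matrix = community_mod.build_matrix(counts)
    write_tsv(out / "community_matrix.tsv", matrix.reset_index())
    ranking = community_mod.rank_top_families(matrix, n=config.top_n)
    write_tsv(out / "top_families.tsv", ranking)
    specimen_totals = barcode_frame.groupby("family").size()
    samples_present = (counts > 0).sum(axis=0)
    stats_matrix = community_mod.apply_exclusions(
        matrix,
        specimen_totals,
        samples_present,
        min_specimens=config.min_specimens,
        min_samples=config.min_samples,
    )
    adj_r2 = community_mod.variance_explained_by_taxon(
        stats_matrix, offset=config.log_offset
    )
    pca = community_mod.pca_relative_eigenvalues(stats_matrix)
    incidence = (
        barcode_frame.groupby(["trap", "cluster"]).size().unstack(fill_value=0) > 0
    )
    turnover = community_mod.turnover_single_site(incidence)
    report.statistics.update(
        {
            "adjusted_r2_family": adj_r2,
            "relative_eigenvalues": pca.relative_eigenvalues.tolist(),
            "turnover_single_site": turnover,
            "top_families": ranking,
        }
    )

    # --- neglect ----------------------------------------------------------
    if config.neglect:
        biblio = synthio.simulate_bibliography(
            synthio.BiblioScenario(
                n_families=config.n_families,
                intensity=config.biblio_intensity,
                author_pool=config.biblio_author_pool,
                seed=config.seed + 2,
            )
        )
        write_tsv(out / "bibliography.tsv", biblio)
        table, _ = neglect.descriptions_per_decade(biblio)
        described = biblio.groupby("family").size()
        ni_rows = []
        for family, n_motu in per_family.items():
            four_decade = int(described.get(family, 0))
            n_sp = max(1, int(round(four_decade * (1 + config.described_backlog_factor))))
            ni_rows.append(
                {
                    "family": family,
                    "n_motu": int(n_motu),
                    "n_sp": n_sp,
                    "ni": neglect.neglect_index(int(n_motu), n_sp),
                }
            )
        ni_table = pd.DataFrame(ni_rows)
        write_tsv(out / "ni_table.tsv", ni_table)
        scores = neglect.author_scores(biblio)
        write_tsv(out / "author_scores.tsv", scores)
        dedicated = neglect.count_dedicated_authors(scores, s_threshold=config.s_threshold)
        write_tsv(out / "dedicated_authors.tsv", dedicated.reset_index())
        ni_by_family = ni_table.set_index("family")["ni"]
        table = table.reindex(ni_by_family.index, fill_value=0)
        r, n_pairs, p = neglect.neglect_activity_correlation(
            table, ni_by_family, zero_offset=config.zero_offset
        )
        report.statistics.update(
            {
                "ni_table": ni_table,
                "neglect_activity_r": r,
                "neglect_activity_n": n_pairs,
                "dedicated_authors": dedicated,
            }
        )

    (out / "report.json").write_text(report.to_json())
    return report
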