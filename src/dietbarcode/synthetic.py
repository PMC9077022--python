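"""Ground-truth simulation: reference libraries, mock prey communities,
camera-recorded deliveries and paired amplicon reads.

The generator emulates the data a camera-validated diet-metabarcoding study
produces: a local COI-like barcode library with a 7-rank taxonomy, a mock
arthropod community with known biomass proportions, nest-camera sessions
whose prey deliveries are size-scored with imperfect taxonomic precision,
and Illumina-style paired reads whose per-taxon counts are proportional to
biomass times a per-taxon amplification efficiency.  Nuisance processes
(per-base sequencing error, two-parent chimeras, host reads, low-level
contamination shared with negative extraction controls) are all seedable
knobs, so each downstream stage can be tested against known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .align import revcomp
from .amplicon import ReadPair

# 7-rank taxonomy used everywhere downstream
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: Arthropod orders treated as (ecto)parasites / secondary prey.
PARASITE_ORDERS = frozenset(
    {"Mesostigmata", "Prostigmata", "Sarcoptiformes", "Siphonaptera", "Trombidiformes"}
)

# Name pools for synthetic libraries.  Real arthropod order names are used so
# that parasite exclusion and class pruning behave as they would on real data.
_PREY_ORDERS = [
    ("Diptera", "Insecta"),
    ("Lepidoptera", "Insecta"),
    ("Coleoptera", "Insecta"),
    ("Hymenoptera", "Insecta"),
    ("Hemiptera", "Insecta"),
    ("Araneae", "Arachnida"),
    ("Isopoda", "Malacostraca"),
    ("Collembola", "Insecta"),
    ("Neuroptera", "Insecta"),
    ("Trichoptera", "Insecta"),
    ("Orthoptera", "Insecta"),
    ("Psocoptera", "Insecta"),
    ("Lithobiomorpha", "Chilopoda"),
    ("Julida", "Diplopoda"),
]
_PARASITE_ORDER_POOL = [
    ("Trombidiformes", "Arachnida"),
    ("Mesostigmata", "Arachnida"),
    ("Siphonaptera", "Insecta"),
    ("Prostigmata", "Arachnida"),
    ("Sarcoptiformes", "Arachnida"),
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigurationError(ValueError):
    """Raised when simulation parameters are inconsistent."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RefRecord:
    """One reference barcode with a 7-rank lineage.

    Ranks may be empty strings below the record's precision level; kingdom
    through order are always populated.
    """

    accession: str
    lineage: tuple[str, ...]
    sequence: str

    def __post_init__(self):
        if len(self.lineage) != 7:
            raise ConfigurationError(f"{self.accession}: lineage must have 7 ranks")
        if any(not r for r in self.lineage[:4]):
            raise ConfigurationError(
                f"{self.accession}: kingdom..order ranks must be non-empty"
            )
        if set(self.sequence) - set("ACGT"):
            raise ConfigurationError(f"{self.accession}: sequence alphabet must be ACGT")

    def rank(self, name: str) -> str:
        return self.lineage[RANKS.index(name)]


@dataclass(frozen=True)
class CommunityMember:
    ref: RefRecord
    biomass_proportion: float
    amplification_efficiency: float
    mean_item_size: float

    @property
    def is_parasite(self) -> bool:
        return self.ref.rank("order") in PARASITE_ORDERS


@dataclass(frozen=True)
class MockCommunity:
    """Ground-truth community: the recovery target for end-to-end tests."""

    members: tuple[CommunityMember, ...]
    host_ref: RefRecord

    def __post_init__(self):
        total = sum(m.biomass_proportion for m in self.members)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"biomass proportions sum to {total}, not 1")
        if any(m.amplification_efficiency <= 0 for m in self.members):
            raise ConfigurationError("amplification efficiencies must be > 0")

    @property
    def read_weights(self) -> np.ndarray:
        """Expected read proportions: biomass x amplification efficiency."""
        w = np.array(
            [m.biomass_proportion * m.amplification_efficiency for m in self.members]
        )
        return w / w.sum()


@dataclass(frozen=True)
class CameraItem:
    """One prey delivery scored from camera footage."""

    session_id: str
    item_id: str
    lineage: tuple[str, ...]
    size_multiplier: float

    def __post_init__(self):
        if not (0.04 <= self.size_multiplier <= 6.0):
            raise ConfigurationError(
                f"size multiplier {self.size_multiplier} outside [0.04, 6.0]"
            )


@dataclass(frozen=True)
class SimulationConfig:
    """Read-simulation knobs.  Fixed seed implies byte-identical output."""

    read_depth_per_sample: int = 10_000
    per_base_error_rate: float = 0.0
    chimera_rate: float = 0.0
    host_read_fraction: float = 0.0
    control_contamination_reads: int = 0
    sample_contamination_reads: int = 0
    read_length: int = 300
    overlap: int = 16
    quality_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("per_base_error_rate", "chimera_rate", "host_read_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name}={v} is not a probability")
        if self.read_depth_per_sample < 0:
            raise ConfigurationError("read depth must be >= 0")
        if self.control_contamination_reads < 0 or self.sample_contamination_reads < 0:
            raise ConfigurationError("contamination read counts must be >= 0")
        if self.read_length <= 0 or self.overlap <= 0:
            raise ConfigurationError("read_length and overlap must be positive")


@dataclass
class SimulatedSample:
    """Paired reads for one sample plus its negative control and truth table."""

    sample_id: str
    pairs: list[ReadPair]
    control_pairs: list[ReadPair]
    truth: pd.DataFrame  # read_id, sample, category, source


# ---------------------------------------------------------------------------
# Sequence helpers
# ---------------------------------------------------------------------------

def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _mutate(codes: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute ``fraction`` of positions with a different base."""
    n = int(round(fraction * codes.size))
    out = codes.copy()
    if n == 0:
        return out
    pos = rng.choice(codes.size, size=n, replace=False)
    out[pos] = (out[pos] + rng.integers(1, 4, size=n)) % 4
    return out


DEFAULT_DIVERGENCE = {"order": 0.30, "family": 0.15, "genus": 0.08, "species": 0.01}


# ---------------------------------------------------------------------------
# Reference library
# ---------------------------------------------------------------------------

def generate_reference_library(
    n_orders: int,
    families_per_order: int = 2,
    genera_per_family: int = 2,
    amplicon_length: int = 270,
    divergence: dict[str, float] | None = None,
    seed: int = 0,
    species_per_genus: int = 1,
    n_parasite_orders: int = 0,
) -> tuple[list[RefRecord], pd.DataFrame]:
    """Generate a hierarchically diverged barcode library with taxonomy.

    Sequences are produced by mutating a random root sequence along the
    taxonomic hierarchy, so that within-genus identity stays above the OTU
    radius (97%) while between-genus identity falls well below 94%.

    Returns the records plus a taxonomy table (accession + 7 ranks).
    """
    if n_orders < 1:
        raise ConfigurationError("n_orders must be >= 1")
    if n_parasite_orders > min(n_orders, len(_PARASITE_ORDER_POOL)):
        raise ConfigurationError("too many parasite orders requested")
    div = dict(DEFAULT_DIVERGENCE)
    if divergence:
        div.update(divergence)
    if any(not (0.0 <= v <= 1.0) for v in div.values()):
        raise ConfigurationError("divergence fractions must lie in [0, 1]")
    if div["genus"] <= 0.06:
        raise ConfigurationError(
            "genus-level divergence must exceed twice the 3% OTU radius"
        )
    n_prey = n_orders - n_parasite_orders
    if n_prey > len(_PREY_ORDERS):
        raise ConfigurationError(f"at most {len(_PREY_ORDERS)} prey orders supported")

    rng = np.random.default_rng(seed)
    root = rng.integers(0, 4, size=amplicon_length).astype(np.uint8)
    order_pool = _PARASITE_ORDER_POOL[:n_parasite_orders] + _PREY_ORDERS[:n_prey]

    records: list[RefRecord] = []
    acc = 0
    for order_name, class_name in order_pool:
        order_seq = _mutate(root, div["order"], rng)
        for fi in range(families_per_order):
            family_name = f"{order_name[:4]}idae{fi + 1}"
            family_seq = _mutate(order_seq, div["family"], rng)
            for gi in range(genera_per_family):
                genus_name = f"{order_name[:3]}genus{fi + 1}{gi + 1}"
                genus_seq = _mutate(family_seq, div["genus"], rng)
                for si in range(species_per_genus):
                    species_seq = _mutate(genus_seq, div["species"], rng)
                    acc += 1
                    records.append(
                        RefRecord(
                            accession=f"REF{acc:05d}",
                            lineage=(
                                "Animalia",
                                "Arthropoda",
                                class_name,
                                order_name,
                                family_name,
                                genus_name,
                                f"{genus_name} sp{si + 1}",
                            ),
                            sequence=_codes_to_str(species_seq),
                        )
                    )
    taxonomy = pd.DataFrame(
        [(r.accession, *r.lineage) for r in records],
        columns=["accession", *RANKS],
    )
    return records, taxonomy


def host_reference(amplicon_length: int = 270, seed: int = 0) -> RefRecord:
    """A single avian host barcode, unrelated to the arthropod library."""
    rng = np.random.default_rng([seed, 0xB17D])
    seq = _codes_to_str(rng.integers(0, 4, size=amplicon_length).astype(np.uint8))
    return RefRecord(
        accession="HOST00001",
        lineage=(
            "Animalia", "Chordata", "Aves", "Passeriformes",
            "Muscicapidae", "Ficedula", "Ficedula hypoleuca",
        ),
        sequence=seq,
    )


# ---------------------------------------------------------------------------
# Mock community
# ---------------------------------------------------------------------------

def generate_mock_diet(
    library: list[RefRecord],
    n_taxa: int,
    concentration: float = 1.0,
    seed: int = 0,
    *,
    amplification_sd: float = 0.3,
    size_log_mean: float = math.log(0.5),
    size_log_sd: float = 0.8,
    host_ref: RefRecord | None = None,
    require_parasite: bool = False,
) -> MockCommunity:
    """Draw a ground-truth diet community from a reference library.

    Biomass proportions come from a symmetric Dirichlet(concentration);
    amplification efficiencies are lognormal(0, amplification_sd); mean item
    sizes are lognormal, clipped to the camera scoring range [0.04, 6.0].
    Members are spread across orders so order-level recovery is informative.
    """
    if n_taxa > len(library):
        raise ConfigurationError(f"n_taxa={n_taxa} exceeds library size {len(library)}")
    if n_taxa < 1:
        raise ConfigurationError("n_taxa must be >= 1")
    rng = np.random.default_rng(seed)

    # round-robin over orders for maximal order diversity, deterministic
    by_order: dict[str, list[RefRecord]] = {}
    for rec in library:
        by_order.setdefault(rec.rank("order"), []).append(rec)
    orders = sorted(by_order)
    for o in orders:
        rng.shuffle(by_order[o])
    chosen: list[RefRecord] = []
    while len(chosen) < n_taxa:
        for o in orders:
            if by_order[o] and len(chosen) < n_taxa:
                chosen.append(by_order[o].pop())
    if require_parasite and not any(r.rank("order") in PARASITE_ORDERS for r in chosen):
        pool = [r for recs in by_order.values() for r in recs
                if r.rank("order") in PARASITE_ORDERS]
        if not pool:
            raise ConfigurationError("library contains no parasite-order records")
        chosen[-1] = pool[0]

    props = rng.dirichlet(np.full(n_taxa, concentration))
    props = props / props.sum()
    effs = rng.lognormal(0.0, amplification_sd, size=n_taxa) if amplification_sd > 0 \
        else np.ones(n_taxa)
    sizes = np.clip(rng.lognormal(size_log_mean, size_log_sd, size=n_taxa), 0.04, 6.0)
    members = tuple(
        CommunityMember(rec, float(p), float(e), float(s))
        for rec, p, e, s in zip(chosen, props, effs, sizes)
    )
    if host_ref is None:
        host_ref = host_reference(len(library[0].sequence), seed)
    return MockCommunity(members=members, host_ref=host_ref)


# ---------------------------------------------------------------------------
# Camera sessions
# ---------------------------------------------------------------------------

#: Default probability that a camera item is resolved exactly to a rank;
#: the remainder (here 0.10) is scored "unknown".  Family-or-worse precision
#: then affects ~35% of items, comparable to field camera scoring.
DEFAULT_RANK_PRECISION = {"order": 0.25, "family": 0.35, "genus": 0.20, "species": 0.10}

_PRECISION_LEVELS = ("order", "family", "genus", "species")


def simulate_camera_session(
    community: MockCommunity,
    n_items: int,
    rank_precision_probs: dict[str, float] | None = None,
    size_noise_sd: float = 0.3,
    seed: int = 0,
    session_id: str = "CAM01",
) -> list[CameraItem]:
    """Draw prey deliveries for one camera session.

    Delivery probability is proportional to biomass / mean item size, so that
    size-multiplier-weighted counts (RSBC) recover biomass by construction
    while raw counts over-represent small prey.  Parasite-order members are
    secondary prey and never appear on camera.  Each item's lineage is
    truncated at a rank drawn from ``rank_precision_probs`` (probability of
    resolving exactly to that rank; remaining mass is scored "unknown").
    """
    if n_items < 0:
        raise ConfigurationError("n_items must be >= 0")
    probs = dict(DEFAULT_RANK_PRECISION if rank_precision_probs is None
                 else rank_precision_probs)
    level_p = np.array([probs.get(r, 0.0) for r in _PRECISION_LEVELS])
    if level_p.sum() > 1.0 + 1e-9:
        raise ConfigurationError("rank precision probabilities sum above 1")
    level_p = np.append(level_p, max(0.0, 1.0 - level_p.sum()))  # last = unknown

    rng = np.random.default_rng(seed)
    prey = [m for m in community.members if not m.is_parasite]
    if not prey:
        raise ConfigurationError("community has no non-parasite members")
    w = np.array([m.biomass_proportion / m.mean_item_size for m in prey])
    w = w / w.sum()

    idx = rng.choice(len(prey), size=n_items, p=w)
    sizes = np.clip(
        np.array([prey[i].mean_item_size for i in idx])
        * np.exp(rng.normal(0.0, size_noise_sd, size=n_items)),
        0.04, 6.0,
    )
    levels = rng.choice(len(level_p), size=n_items, p=level_p)

    items = []
    for k, (i, size, lev) in enumerate(zip(idx, sizes, levels)):
        lineage = list(prey[i].ref.lineage)
        if lev == len(_PRECISION_LEVELS):  # unknown: class and below unresolved
            lineage[2:] = [""] * 5
        else:
            depth = 4 + lev  # keep kingdom..order plus `lev` extra ranks
            lineage[depth:] = [""] * (7 - depth)
        items.append(
            CameraItem(
                session_id=session_id,
                item_id=f"{session_id}_i{k + 1:04d}",
                lineage=tuple(lineage),
                size_multiplier=float(size),
            )
        )
    return items


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _phred_for(p: float) -> int:
    if p <= 0:
        return 41
    return int(np.clip(round(-10.0 * math.log10(p)), 2, 41))


def _make_reads(
    templates: np.ndarray,
    read_ids: list[str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[ReadPair]:
    """Turn template matrix (N x amplicon) into paired reads with errors."""
    n, amplicon = templates.shape
    rlen = min(config.read_length, amplicon)
    fwd = templates[:, :rlen].copy()
    rev = (3 - templates[:, ::-1])[:, :rlen].copy()  # revcomp then clip

    p = config.per_base_error_rate
    pairs = []
    q0 = _phred_for(p)
    for mat in (fwd, rev):
        if p > 0 and config.quality_jitter > 0:
            qs = np.clip(
                np.rint(q0 + rng.normal(0.0, config.quality_jitter, mat.shape)),
                2, 41,
            ).astype(np.uint8)
            perr = 10.0 ** (-qs / 10.0)
            mask = rng.random(mat.shape) < perr
        else:
            qs = np.full(mat.shape, q0, dtype=np.uint8)
            mask = rng.random(mat.shape) < p if p > 0 else np.zeros(mat.shape, bool)
        if mask.any():
            shift = rng.integers(1, 4, size=int(mask.sum()))
            mat[mask] = (mat[mask] + shift) % 4
        mat_q = qs + 33
        if mat is fwd:
            fq, fqual = mat, mat_q
        else:
            rq, rqual = mat, mat_q
    for i in range(n):
        pairs.append(
            ReadPair(
                id=read_ids[i],
                fwd_seq=_codes_to_str(fq[i]),
                rev_seq=_codes_to_str(rq[i]),
                fwd_qual=fqual[i].tobytes().decode("ascii"),
                rev_qual=rqual[i].tobytes().decode("ascii"),
            )
        )
    return pairs


def simulate_reads(
    community: MockCommunity,
    config: SimulationConfig,
    sample_id: str = "S01",
    proportions: np.ndarray | None = None,
    contaminant_accessions: list[str] | None = None,
) -> SimulatedSample:
    """Simulate one sample's paired reads, its negative control, and truth.

    Expected per-taxon read counts are proportional to biomass x
    amplification efficiency (or to ``proportions`` when given).  Chimeras
    are two-parent splices at a uniform breakpoint in [30%, 70%] of the
    amplicon; host reads come from the single avian host reference; the
    negative control contains only contamination reads drawn from a
    designated contaminant subset of the community.
    """
    amplicon = len(community.members[0].ref.sequence)
    if amplicon > 2 * config.read_length - config.overlap:
        raise ConfigurationError(
            f"amplicon ({amplicon} bp) not reconstructable from "
            f"{config.read_length} bp pairs with overlap {config.overlap}"
        )
    rng = np.random.default_rng(config.seed)
    members = community.members
    templ = np.stack(
        [np.frombuffer(m.ref.sequence.encode(), np.uint8) for m in members]
    )
    templ = _encode_matrix(templ)
    host = _encode_matrix(
        np.frombuffer(community.host_ref.sequence.encode(), np.uint8)[None, :]
    )[0]

    w = community.read_weights if proportions is None else (
        np.asarray(proportions, float) / np.sum(proportions)
    )
    depth = config.read_depth_per_sample
    n_chim, n_host, n_taxon = rng.multinomial(
        depth, [config.chimera_rate, config.host_read_fraction,
                1.0 - config.chimera_rate - config.host_read_fraction]
    )
    taxon_counts = rng.multinomial(n_taxon, w)

    rows, sources, cats = [], [], []
    for i, c in enumerate(taxon_counts):
        if c:
            rows.append(np.repeat(templ[i][None, :], c, axis=0))
            sources.extend([members[i].ref.accession] * c)
            cats.extend(["taxon"] * c)
    if n_chim:
        lo, hi = int(0.3 * amplicon), int(0.7 * amplicon)
        chim = np.empty((n_chim, amplicon), dtype=np.uint8)
        for j in range(n_chim):
            a, b = rng.choice(len(members), size=2, replace=False, p=w)
            bp = int(rng.integers(lo, hi + 1))
            chim[j, :bp] = templ[a, :bp]
            chim[j, bp:] = templ[b, bp:]
            sources.append(f"{members[a].ref.accession}|{members[b].ref.accession}")
            cats.append("chimera")
        rows.append(chim)
    if n_host:
        rows.append(np.repeat(host[None, :], n_host, axis=0))
        sources.extend([community.host_ref.accession] * n_host)
        cats.extend(["host"] * n_host)

    contam_idx = _contaminant_indices(community, contaminant_accessions)
    if config.sample_contamination_reads:
        counts = rng.multinomial(
            config.sample_contamination_reads,
            np.full(len(contam_idx), 1.0 / len(contam_idx)),
        )
        for i, c in zip(contam_idx, counts):
            if c:
                rows.append(np.repeat(templ[i][None, :], c, axis=0))
                sources.extend([members[i].ref.accession] * c)
                cats.extend(["contaminant"] * c)

    all_templates = (
        np.concatenate(rows) if rows else np.empty((0, amplicon), np.uint8)
    )
    read_ids = [f"{sample_id}_r{i + 1:06d}" for i in range(len(all_templates))]
    pairs = _make_reads(all_templates, read_ids, config, rng)

    # negative control
    ctrl_rows, ctrl_sources = [], []
    if config.control_contamination_reads:
        counts = rng.multinomial(
            config.control_contamination_reads,
            np.full(len(contam_idx), 1.0 / len(contam_idx)),
        )
        for i, c in zip(contam_idx, counts):
            if c:
                ctrl_rows.append(np.repeat(templ[i][None, :], c, axis=0))
                ctrl_sources.extend([members[i].ref.accession] * c)
    ctrl_templates = (
        np.concatenate(ctrl_rows) if ctrl_rows else np.empty((0, amplicon), np.uint8)
    )
    ctrl_ids = [f"{sample_id}_neg_r{i + 1:05d}" for i in range(len(ctrl_templates))]
    ctrl_pairs = _make_reads(ctrl_templates, ctrl_ids, config, rng)

    truth = pd.DataFrame(
        {
            "read_id": read_ids + ctrl_ids,
            "sample": [sample_id] * len(read_ids)
            + [f"{sample_id}_NEG"] * len(ctrl_ids),
            "category": cats + ["contaminant"] * len(ctrl_ids),
            "source": sources + ctrl_sources,
        }
    )
    return SimulatedSample(sample_id, pairs, ctrl_pairs, truth)


def _encode_matrix(ascii_mat: np.ndarray) -> np.ndarray:
    """Map ASCII ACGT bytes to 0..3 codes."""
    lut = np.zeros(256, dtype=np.uint8)
    lut[ord("A")], lut[ord("C")], lut[ord("G")], lut[ord("T")] = 0, 1, 2, 3
    return lut[ascii_mat]


def _contaminant_indices(
    community: MockCommunity, accessions: list[str] | None
) -> list[int]:
    if accessions is None:
        # designated subset: up to 7 lowest-biomass members
        order = np.argsort([m.biomass_proportion for m in community.members])
        return [int(i) for i in order[: min(7, len(order))]]
    accset = set(accessions)
    idx = [i for i, m in enumerate(community.members) if m.ref.accession in accset]
    if not idx:
        raise ConfigurationError("no community member matches contaminant accessions")
    return idx


# ---------------------------------------------------------------------------
# Writers (plain deterministic text output)
# ---------------------------------------------------------------------------

def write_fasta(records: list[RefRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.accession}\n{r.sequence}\n")


def write_paired_fastq(pairs: list[ReadPair], r1_path, r2_path) -> None:
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.id}/1\n{p.fwd_seq}\n+\n{p.fwd_qual}\n")
            f2.write(f"@{p.id}/2\n{p.rev_seq}\n+\n{p.rev_qual}\n")


def write_taxonomy(taxonomy: pd.DataFrame, path) -> None:
    taxonomy.to_csv(path, sep="\t", index=False)


def write_camera_tsv(items: list[CameraItem], path) -> None:
    rows = [
        (it.session_id, it.item_id, *it.lineage, it.size_multiplier) for it in items
    ]
    pd.DataFrame(
        rows, columns=["session_id", "item_id", *RANKS, "size_multiplier"]
    ).to_csv(path, sep="\t", index=False)


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_paired_fastq(r1_path, r2_path) -> list[ReadPair]:
    """Load paired FASTQ (Phred+33) back into ReadPair objects."""
    from Bio import SeqIO

    pairs = []
    for rec1, rec2 in zip(
        SeqIO.parse(str(r1_path), "fastq"), SeqIO.parse(str(r2_path), "fastq")
    ):
        q1 = rec1.letter_annotations["phred_quality"]
        q2 = rec2.letter_annotations["phred_quality"]
        rid = rec1.id.rsplit("/", 1)[0]
        pairs.append(
            ReadPair(
                id=rid,
                fwd_seq=str(rec1.seq),
                rev_seq=str(rec2.seq),
                fwd_qual="".join(chr(q + 33) for q in q1),
                rev_qual="".join(chr(q + 33) for q in q2),
            )
        )
    return pairs
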