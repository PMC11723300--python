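"""Seeded generators for pipeline-shaped synthetic inputs.

The generators emulate the structure of a regional barcoding survey: three
markers with distinct length, GC and divergence profiles, a
family/genus/species hierarchy with one-to-several vouchers per species,
reference libraries with conspecific/congeneric/confamilial records (and
controllable omission of conspecifics), and per-species AHP indicator
tables.

Sequence evolution is a two-rate (transition/transversion) per-site
substitution process on a fixed-length alignment — the minimal model under
which the Kimura 2-parameter distance is the matched estimator, which makes
parameter recovery a meaningful test. Species, genus and family ancestors
radiate from their parent ancestor in a star phylogeny at each level, so
the configured between-species divergence is a floor on inter-specific
distance: with ``gap_present`` the generator guarantees (up to binomial
site-sampling noise) that intraspecific distances sit below interspecific
ones. Indels, recombination and alignment error are not modelled;
sequences are generated already aligned.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from barcodekit.seqio import BarcodeRecord, MarkerDataset
from barcodekit.identification import ReferenceLibrary

_BASES = np.array(list("ACGT"))
#: transition partner of each base index (A<->G, C<->T)
_TS_PARTNER = np.array([2, 3, 0, 1])
#: the two transversion partners of each base index
_TV_PARTNERS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])


@dataclass(frozen=True)
class MarkerProfile:
    """Divergence/GC profile of one marker.

    Divergences are target pairwise p-distances: ``intra_divergence``
    between conspecific individuals, ``inter_divergence`` between congeneric
    species (the floor on inter-specific distance). ``genus_divergence`` and
    ``family_divergence`` add further separation across genera and families.
    ``ts_tv_ratio`` is the expected transition/transversion ratio.
    """

    name: str
    length: int = 800
    gc: float = 0.45
    intra_divergence: float = 0.01
    inter_divergence: float = 0.12
    genus_divergence: float | None = None
    family_divergence: float | None = None
    ts_tv_ratio: float = 2.0

    def __post_init__(self) -> None:
        if self.length < 100:
            raise ValueError("marker length must be >= 100")
        if not (0.0 < self.gc < 1.0):
            raise ValueError("gc must be in (0, 1)")
        for d in (self.intra_divergence, self.inter_divergence):
            if not (0.0 < d < 1.0):
                raise ValueError("divergences must be in (0, 1)")

    @property
    def genus_div(self) -> float:
        return self.genus_divergence if self.genus_divergence is not None else self.inter_divergence

    @property
    def family_div(self) -> float:
        return (
            self.family_divergence
            if self.family_divergence is not None
            else 1.5 * self.inter_divergence
        )


def default_markers() -> list[MarkerProfile]:
    """Three markers shaped like the standard plant barcodes.

    ITS: nuclear, GC-rich, fast; matK: plastid, AT-rich, fast; rbcL:
    plastid, conservative. Mean inter-specific distances order as
    ITS ~ matK > rbcL.
    """
    return [
        MarkerProfile(name="ITS", length=700, gc=0.56, intra_divergence=0.010,
                      inter_divergence=0.14),
        MarkerProfile(name="matK", length=800, gc=0.34, intra_divergence=0.010,
                      inter_divergence=0.13),
        MarkerProfile(name="rbcL", length=600, gc=0.44, intra_divergence=0.005,
                      inter_divergence=0.06),
    ]


@dataclass(frozen=True)
class SimConfig:
    """Shape and divergence structure of a simulated survey.

    The default mirrors a small survey: 3 families x 2 genera x 2 species
    (12 species) with 1-3 vouchers each, three markers, and a barcoding gap
    present at every marker.
    """

    seed: int = 0
    n_families: int = 3
    genera_per_family: int = 2
    species_per_genus: int = 2
    samples_per_species: tuple[int, int] = (1, 3)
    markers: tuple[MarkerProfile, ...] = field(default_factory=lambda: tuple(default_markers()))
    gap_present: bool = True
    #: per-criterion probability weights over score levels (id -> weights);
    #: criteria not listed sample uniformly over their levels.
    ahp_level_weights: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.samples_per_species
        if not (1 <= lo <= hi):
            raise ValueError("samples_per_species must satisfy 1 <= lo <= hi")
        if min(self.n_families, self.genera_per_family, self.species_per_genus) < 1:
            raise ValueError("taxonomy counts must be >= 1")
        if self.gap_present:
            for m in self.markers:
                # intra pairs reach ~intra_divergence; inter pairs floor at
                # ~inter_divergence. Overlapping targets contradict the flag.
                if m.intra_divergence >= m.inter_divergence:
                    raise ValueError(
                        f"marker {m.name}: gap_present requires "
                        "intra_divergence < inter_divergence"
                    )

    @property
    def n_species(self) -> int:
        return self.n_families * self.genera_per_family * self.species_per_genus

    def with_gap_absent(self) -> "SimConfig":
        """A no-gap variant of the same survey.

        Intraspecific variation is widened past the interspecific target
        while species ancestors are drawn much closer together, so the two
        distance distributions genuinely interleave.
        """
        markers = tuple(
            replace(
                m,
                intra_divergence=max(m.inter_divergence * 1.5, m.intra_divergence),
                inter_divergence=m.inter_divergence,
            )
            for m in self.markers
        )
        return replace(self, markers=markers, gap_present=False)


def _taxa(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Species table: species, genus, family, n_samples."""
    rows = []
    lo, hi = config.samples_per_species
    for f in range(1, config.n_families + 1):
        family = f"Fam{f}"
        for g in range(1, config.genera_per_family + 1):
            genus = f"{family}_Gen{g}"
            for s in range(1, config.species_per_genus + 1):
                rows.append(
                    {
                        "species": f"{genus}_sp{s}",
                        "genus": genus,
                        "family": family,
                        "n_samples": int(rng.integers(lo, hi + 1)),
                    }
                )
    return pd.DataFrame(rows)


def _root_sequence(profile: MarkerProfile, rng: np.random.Generator) -> np.ndarray:
    p = np.array(
        [(1 - profile.gc) / 2, profile.gc / 2, profile.gc / 2, (1 - profile.gc) / 2]
    )
    return rng.choice(4, size=profile.length, p=p)


def _mutate(seq: np.ndarray, rate: float, profile: MarkerProfile, rng: np.random.Generator) -> np.ndarray:
    """Substitute a Binomial(length, rate) set of sites, transitions favored."""
    out = seq.copy()
    n_mut = rng.binomial(len(seq), min(rate, 1.0))
    if n_mut == 0:
        return out
    sites = rng.choice(len(seq), size=n_mut, replace=False)
    ts_prob = profile.ts_tv_ratio / (profile.ts_tv_ratio + 1.0)
    is_ts = rng.random(n_mut) < ts_prob
    current = out[sites]
    new = np.where(
        is_ts,
        _TS_PARTNER[current],
        _TV_PARTNERS[current, rng.integers(0, 2, size=n_mut)],
    )
    out[sites] = new
    return out


def _decode(seq: np.ndarray) -> str:
    return "".join(_BASES[seq])


def _marker_state(
    config: SimConfig, profile: MarkerProfile, taxa: pd.DataFrame, rng: np.random.Generator
) -> tuple[list[BarcodeRecord], dict[str, np.ndarray]]:
    """Voucher records plus the per-species ancestor sequences."""
    root = _root_sequence(profile, rng)
    fam_anc = {
        fam: _mutate(root, profile.family_div / 2, profile, rng)
        for fam in taxa["family"].unique()
    }
    gen_anc = {}
    for genus, fam in taxa.drop_duplicates("genus")[["genus", "family"]].itertuples(index=False):
        gen_anc[genus] = _mutate(fam_anc[fam], profile.genus_div / 2, profile, rng)
    sp_anc = {}
    records = []
    for row in taxa.itertuples(index=False):
        if config.gap_present:
            sp_rate = profile.inter_divergence / 2
        else:
            # overlapping regime: congeners barely diverged
            sp_rate = rng.uniform(0.0, profile.inter_divergence / 4)
        anc = _mutate(gen_anc[row.genus], sp_rate, profile, rng)
        sp_anc[row.species] = anc
        for k in range(1, row.n_samples + 1):
            if config.gap_present:
                rate = profile.intra_divergence / 2
            else:
                # individuals wander up to the interspecific range
                rate = rng.uniform(0.0, profile.intra_divergence / 2)
            records.append(
                BarcodeRecord(
                    sample_id=f"{row.species}_v{k}",
                    species=row.species,
                    genus=row.genus,
                    family=row.family,
                    marker=profile.name,
                    sequence=_decode(_mutate(anc, rate, profile, rng)),
                )
            )
    return records, sp_anc


def _streams(config: SimConfig) -> dict[str, np.random.Generator]:
    """Named, independent, deterministic RNG streams for one config."""
    ss = np.random.SeedSequence(config.seed)
    names = ["taxa"] + [f"marker:{m.name}" for m in config.markers]
    names += [f"library:{m.name}" for m in config.markers] + ["ahp"]
    children = ss.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def simulate_sequences(config: SimConfig) -> tuple[dict[str, MarkerDataset], pd.DataFrame]:
    """Per-marker aligned datasets plus the voucher taxonomy table."""
    streams = _streams(config)
    taxa = _taxa(config, streams["taxa"])
    datasets = {}
    taxonomy_rows = []
    for profile in config.markers:
        records, _ = _marker_state(config, profile, taxa, streams[f"marker:{profile.name}"])
        datasets[profile.name] = MarkerDataset(
            marker=profile.name, records=records, aligned=True
        )
    for rec in datasets[config.markers[0].name]:
        taxonomy_rows.append(
            {
                "sample_id": rec.sample_id,
                "species": rec.species,
                "genus": rec.genus,
                "family": rec.family,
            }
        )
    return datasets, pd.DataFrame(taxonomy_rows)


def simulate_reference_library(
    config: SimConfig,
    marker: str | None = None,
    n_refs_per_species: int = 1,
    omit_conspecifics: tuple[str, ...] = (),
) -> ReferenceLibrary:
    """A reference library consistent with :func:`simulate_sequences`.

    For every species the library holds ``n_refs_per_species`` independent
    conspecific records drawn around the same species ancestor the vouchers
    came from; the other species double as congeneric and confamilial
    decoys. Species in ``omit_conspecifics`` get no conspecific records,
    emulating gaps in public reference databases.
    """
    streams = _streams(config)
    taxa = _taxa(config, streams["taxa"])
    if marker is None:
        marker = config.markers[0].name
    profile = next((m for m in config.markers if m.name == marker), None)
    if profile is None:
        raise KeyError(f"no marker named {marker!r} in config")
    _, sp_anc = _marker_state(config, profile, taxa, streams[f"marker:{profile.name}"])
    rng = streams[f"library:{profile.name}"]
    omitted = set(omit_conspecifics)
    records = []
    for row in taxa.itertuples(index=False):
        if row.species in omitted:
            continue
        for k in range(1, n_refs_per_species + 1):
            seq = _mutate(sp_anc[row.species], profile.intra_divergence / 2, profile, rng)
            records.append(
                BarcodeRecord(
                    sample_id=f"{row.species}_ref{k}",
                    species=row.species,
                    genus=row.genus,
                    family=row.family,
                    marker=profile.name,
                    sequence=_decode(seq),
                )
            )
    if not records:
        raise ValueError("library would be empty: every species omitted")
    return ReferenceLibrary(marker=profile.name, records=records)


def simulate_judgment_matrix(
    n: int,
    rng: np.random.Generator,
    noise: float = 0.25,
    max_cr: float = 0.1,
    max_tries: int = 200,
) -> np.ndarray:
    """A random reciprocal pairwise-comparison matrix with acceptable
    consistency.

    A random weight vector generates a consistent matrix, which is then
    perturbed by symmetric log-normal noise (reciprocity preserved
    exactly). Draws are repeated until the consistency ratio falls below
    ``max_cr`` — inconsistent matrices are rejected in AHP practice, so
    only acceptable ones are emulated.
    """
    from barcodekit.ahp import derive_weights

    for _ in range(max_tries):
        w = rng.dirichlet(np.ones(n)) + 0.05
        m = np.outer(w, 1.0 / w)
        eps = rng.normal(0.0, noise, size=(n, n))
        m = m * np.exp(eps - eps.T)
        np.fill_diagonal(m, 1.0)
        _, cons = derive_weights(m)
        if cons.CR < max_cr:
            return m
    raise RuntimeError(f"no acceptable matrix found in {max_tries} tries")


def simulate_ahp_scores(config: SimConfig, scheme) -> pd.DataFrame:
    """Per-species criterion points sampled from configured level weights."""
    streams = _streams(config)
    taxa = _taxa(config, streams["taxa"])
    rng = streams["ahp"]
    rows = []
    for row in taxa.itertuples(index=False):
        entry = {"species": row.species, "family": row.family}
        for crit in scheme:
            weights = config.ahp_level_weights.get(crit.id)
            if weights is None:
                p = None
            else:
                w = np.asarray(weights, dtype=float)
                if len(w) != len(crit.points) or w.sum() <= 0:
                    raise ValueError(f"bad level weights for criterion {crit.id}")
                p = w / w.sum()
            entry[crit.id] = int(rng.choice(crit.points, p=p))
        rows.append(entry)
    return pd.DataFrame(rows)
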