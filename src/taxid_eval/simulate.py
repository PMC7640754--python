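"""Synthetic identification records with the study's statistical structure.

Every identification tool is modelled by a :class:`ToolProfile`: a
multinomial distribution over the match-category vocabulary for the
first-choice outcome, a law for how many suggestions the tool returns,
and a single replicate-dependence parameter ``rho`` — the probability
that a replicate repeats the previous replicate's answer verbatim rather
than redrawing.  ``rho = 0`` gives i.i.d. replicates; ``rho = 1`` makes
all five replicates of a sample identical.

The default configuration mirrors the benchmark design the analysis
stack expects: nine tools, 38 sample images (12 flowers, 3 fruits, 10
leaves, 13 whole plants; 16 herbs, 15 monocots, 7 woody plants), five
replicates each.  The nine default profiles reproduce the published
per-app accuracy spectrum (first-choice accuracy bands, misleading and
wrong-family rates, and mean replicate consistency) so that simulated
data exercise the whole range from strong to weak identifiers.

Randomness is counter-based: each (tool, sample) pair draws from its own
substream spawned from the root seed, so appending a tool or sample never
perturbs the records already generated for the others.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .datamodel import (
    PLANT_PARTS,
    PLANT_TYPES,
    ConfigError,
    IdentificationRecord,
    MatchCategory,
    SampleMeta,
    Suggestion,
    TaxonRef,
    ValidationError,
)

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class ToolProfile:
    """Generative behaviour of one identification tool.

    ``category_probabilities`` is the multinomial over first-choice
    outcomes (must sum to 1).  ``n_suggestions_law`` gives the number of
    suggestions returned (1-4), conditional on an identification being
    returned at all; a drawn ``no_id`` outcome always yields an empty
    record.  ``repeat_probability`` is the verbatim-repeat chance between
    consecutive replicates.
    """

    tool_id: str
    category_probabilities: Mapping[MatchCategory, float]
    n_suggestions_law: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.40, 2: 0.25, 3: 0.20, 4: 0.15}
    )
    repeat_probability: float = 0.5

    def __post_init__(self) -> None:
        probs = dict(self.category_probabilities)
        if any(p < 0 for p in probs.values()):
            raise ConfigError(f"{self.tool_id}: negative category probability")
        total = sum(probs.values())
        if abs(total - 1.0) > _PROB_TOL:
            raise ConfigError(f"{self.tool_id}: category probabilities sum to {total}, not 1")
        law = dict(self.n_suggestions_law)
        if set(law) - {1, 2, 3, 4} or any(p < 0 for p in law.values()):
            raise ConfigError(f"{self.tool_id}: suggestion-count law must cover counts 1-4")
        if abs(sum(law.values()) - 1.0) > _PROB_TOL:
            raise ConfigError(f"{self.tool_id}: suggestion-count law must sum to 1")
        if not 0.0 <= self.repeat_probability <= 1.0:
            raise ConfigError(f"{self.tool_id}: repeat probability must lie in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Design of a simulated benchmark run.

    Defaults mirror the reference design: a synthetic taxonomy large
    enough to draw 38 distinct reference species, five replicates, and
    part/type partitions that sum to the sample count.
    """

    n_families: int = 19
    n_genera_per_family: int = 3
    n_species_per_genus: int = 2
    n_samples: int = 38
    n_replicates: int = 5
    seed: int = 0
    plant_part_counts: Mapping[str, int] = field(
        default_factory=lambda: {"flower": 12, "fruit": 3, "leaf": 10, "plant": 13}
    )
    plant_type_counts: Mapping[str, int] = field(
        default_factory=lambda: {"herb": 16, "monocot": 15, "woody": 7}
    )

    def __post_init__(self) -> None:
        for name in ("n_families", "n_genera_per_family", "n_species_per_genus",
                     "n_samples", "n_replicates"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.n_species < self.n_samples:
            raise ConfigError(
                f"taxonomy holds {self.n_species} species but {self.n_samples} "
                "distinct reference species are required"
            )
        for grouping, counts, levels in (
            ("plant_part_counts", self.plant_part_counts, PLANT_PARTS),
            ("plant_type_counts", self.plant_type_counts, PLANT_TYPES),
        ):
            if set(counts) - set(levels) or any(c < 0 for c in counts.values()):
                raise ConfigError(f"{grouping}: levels must be among {levels}, counts >= 0")
            if sum(counts.values()) != self.n_samples:
                raise ConfigError(
                    f"{grouping} sums to {sum(counts.values())}, expected {self.n_samples}"
                )

    @property
    def n_species(self) -> int:
        return self.n_families * self.n_genera_per_family * self.n_species_per_genus


def generate_taxonomy(config: SimConfig) -> tuple[dict[str, TaxonRef], dict[str, SampleMeta]]:
    """Deterministic synthetic taxonomy plus a sample set with metadata.

    Species names are synthetic binomials (``GenusXY spN``); every
    sample's reference species exists in the taxonomy and samples are
    distinct species drawn without replacement.
    """
    taxonomy: dict[str, TaxonRef] = {}
    for fi in range(config.n_families):
        family = f"Family{fi + 1:02d}aceae"
        for gi in range(config.n_genera_per_family):
            genus = f"Genus{fi + 1:02d}{chr(ord('a') + gi)}"
            for si in range(config.n_species_per_genus):
                name = f"{genus} sp{si + 1}"
                taxonomy[name] = TaxonRef(name, genus, family)

    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    species = list(taxonomy)
    chosen = [species[i] for i in rng.permutation(len(species))[: config.n_samples]]
    part_labels = list(
        itertools.chain.from_iterable(
            [p] * config.plant_part_counts.get(p, 0) for p in PLANT_PARTS
        )
    )
    type_labels = list(
        itertools.chain.from_iterable(
            [t] * config.plant_type_counts.get(t, 0) for t in PLANT_TYPES
        )
    )
    part_labels = [part_labels[i] for i in rng.permutation(config.n_samples)]
    type_labels = [type_labels[i] for i in rng.permutation(config.n_samples)]

    metadata: dict[str, SampleMeta] = {}
    for i, name in enumerate(chosen):
        sample_id = f"S{i + 1:03d}"
        metadata[sample_id] = SampleMeta(sample_id, taxonomy[name], part_labels[i], type_labels[i])
    return taxonomy, metadata


class _TaxonomyIndex:
    """Sibling lookups used to realize concrete names for drawn categories."""

    def __init__(self, taxonomy: Mapping[str, TaxonRef]):
        self.by_family: dict[str, dict[str, list[str]]] = {}
        for taxon in taxonomy.values():
            self.by_family.setdefault(taxon.family, {}).setdefault(taxon.genus, []).append(
                taxon.species_name
            )
        self.families = sorted(self.by_family)

    def sibling_species(self, ref: TaxonRef, rng: np.random.Generator) -> str:
        pool = [s for s in self.by_family[ref.family][ref.genus] if s != ref.species_name]
        return str(rng.choice(pool)) if pool else ref.species_name

    def sibling_genus_species(self, ref: TaxonRef, rng: np.random.Generator) -> str:
        genera = [g for g in sorted(self.by_family[ref.family]) if g != ref.genus]
        if not genera:
            return self.sibling_species(ref, rng)
        genus = str(rng.choice(genera))
        return str(rng.choice(self.by_family[ref.family][genus]))

    def other_family_species(self, ref: TaxonRef, rng: np.random.Generator) -> str:
        families = [f for f in self.families if f != ref.family]
        if not families:
            return self.sibling_genus_species(ref, rng)
        family = str(rng.choice(families))
        genus = str(rng.choice(sorted(self.by_family[family])))
        return str(rng.choice(self.by_family[family][genus]))


def _realize_name(
    category: MatchCategory,
    reference: TaxonRef,
    index: _TaxonomyIndex,
    rng: np.random.Generator,
) -> str:
    if category is MatchCategory.SPECIES_CORRECT:
        return reference.species_name
    if category in (MatchCategory.VERY_CLOSE, MatchCategory.SMALL_GENUS, MatchCategory.GENUS_CORRECT):
        return index.sibling_species(reference, rng)
    if category in (MatchCategory.SIMILAR_GENUS, MatchCategory.FAMILY_CORRECT):
        return index.sibling_genus_species(reference, rng)
    # similar_family / good_try / unknown / misleading: a taxon elsewhere
    return index.other_family_species(reference, rng)


def _draw_attempt(
    profile: ToolProfile,
    reference: TaxonRef,
    index: _TaxonomyIndex,
    rng: np.random.Generator,
    categories: Sequence[MatchCategory],
    cat_probs: np.ndarray,
    count_values: Sequence[int],
    count_probs: np.ndarray,
) -> tuple[Suggestion, ...]:
    first = categories[rng.choice(len(categories), p=cat_probs)]
    if first is MatchCategory.NO_ID:
        return ()
    n = count_values[rng.choice(len(count_values), p=count_probs)]
    suggestions = [Suggestion(1, _realize_name(first, reference, index, rng), first)]
    # later suggestions redraw from the same multinomial, no_id excluded
    mask = np.array([c is not MatchCategory.NO_ID for c in categories])
    if mask.any() and cat_probs[mask].sum() > 0:
        later_probs = cat_probs * mask
        later_probs = later_probs / later_probs.sum()
    else:  # profile is pure no_id; unreachable once first != NO_ID
        later_probs = cat_probs
    for pos in range(2, n + 1):
        cat = categories[rng.choice(len(categories), p=later_probs)]
        suggestions.append(Suggestion(pos, _realize_name(cat, reference, index, rng), cat))
    return tuple(suggestions)


def simulate_records(
    profiles: Sequence[ToolProfile],
    metadata: Mapping[str, SampleMeta],
    taxonomy: Mapping[str, TaxonRef],
    config: SimConfig,
) -> list[IdentificationRecord]:
    """Generate one record per tool x sample x replicate.

    Replicate 1 always redraws; each later replicate repeats the previous
    one verbatim with probability ``rho`` and redraws otherwise.
    Substreams are keyed by (tool index, sample index) so the stream is
    reproducible and extension-stable.
    """
    index = _TaxonomyIndex(taxonomy)
    records: list[IdentificationRecord] = []
    for ti, profile in enumerate(profiles):
        categories = list(profile.category_probabilities)
        cat_probs = np.array([profile.category_probabilities[c] for c in categories], float)
        cat_probs = cat_probs / cat_probs.sum()
        count_values = sorted(profile.n_suggestions_law)
        count_probs = np.array([profile.n_suggestions_law[c] for c in count_values], float)
        count_probs = count_probs / count_probs.sum()
        for si, (sample_id, meta) in enumerate(metadata.items()):
            rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(1, ti, si))
            )
            previous: tuple[Suggestion, ...] | None = None
            for rep in range(1, config.n_replicates + 1):
                if previous is not None and rng.random() < profile.repeat_probability:
                    suggestions = previous
                else:
                    suggestions = _draw_attempt(
                        profile, meta.reference, index, rng,
                        categories, cat_probs, count_values, count_probs,
                    )
                previous = suggestions
                records.append(IdentificationRecord(profile.tool_id, sample_id, rep, suggestions))
    return records


def recover_profile(records: Sequence[IdentificationRecord]) -> tuple[dict[MatchCategory, float], float]:
    """Estimate one tool's multinomial and repeat probability from records.

    The multinomial is estimated from the first replicate of every sample
    (independent draws by construction).  ``rho`` is estimated from the
    fraction of consecutive-replicate pairs with identical first-choice
    category, corrected for chance agreement under the estimated
    multinomial: ``rho_hat = (p_same - s) / (1 - s)`` with
    ``s = sum(p_c^2)``, clipped to [0, 1].
    """
    by_sample: dict[str, dict[int, IdentificationRecord]] = {}
    for rec in records:
        by_sample.setdefault(rec.sample_id, {})[rec.replicate] = rec
    if not by_sample:
        raise ValidationError("no records supplied")
    if any(len(reps) < 2 for reps in by_sample.values()):
        raise ValidationError("profile recovery needs >= 2 replicates per sample")

    counts: dict[MatchCategory, int] = {}
    for reps in by_sample.values():
        cat = reps[min(reps)].first_category
        counts[cat] = counts.get(cat, 0) + 1
    n = sum(counts.values())
    probs = {cat: c / n for cat, c in counts.items()}

    same = 0
    pairs = 0
    for reps in by_sample.values():
        order = sorted(reps)
        for r1, r2 in zip(order, order[1:]):
            pairs += 1
            if reps[r1].first_category == reps[r2].first_category:
                same += 1
    p_same = same / pairs
    s = sum(p * p for p in probs.values())
    if s >= 1.0 - _PROB_TOL:
        # degenerate multinomial: repeats and redraws are indistinguishable
        rho_hat = 1.0 if p_same == 1.0 else 0.0
    else:
        rho_hat = (p_same - s) / (1.0 - s)
    return probs, float(min(1.0, max(0.0, rho_hat)))


# ---------------------------------------------------------------------------
# Default tool profiles
# ---------------------------------------------------------------------------

#: Published per-app summary used to parameterize the default profiles:
#: (% first choice = 100, % >= 80, % >= 50, %mad, %wrong, mean consistency C).
APP_SUMMARY: Mapping[str, tuple[float, float, float, float, float, float]] = {
    "Plant.id": (57, 70, 73, 3, 27, 3.2),
    "Google Lens": (45, 56, 71, 8, 28, 2.9),
    "Seek": (35, 55, 68, 4, 12, 3.4),
    "Flora Incognita": (46, 56, 64, 7, 14, 3.0),
    "PlantNet": (39, 49, 55, 11, 43, 2.5),
    "PlantSnap": (24, 38, 47, 32, 54, 2.1),
    "Candide": (1, 18, 35, 25, 61, 1.6),
    "Bing": (3, 17, 23, 57, 67, 1.3),
    "iPlant": (1, 8, 24, 40, 60, 2.1),
}

#: Tools documented as returning essentially a single answer.
_SINGLE_ANSWER_TOOLS = frozenset({"Seek", "iPlant"})


def profile_from_summary(
    tool_id: str,
    pct_100: float,
    pct_ge_80: float,
    pct_ge_50: float,
    pct_mad: float,
    pct_wrong: float,
    mean_consistency: float,
    single_answer: bool = False,
) -> ToolProfile:
    """Build a generative profile from headline accuracy/error percentages.

    The accuracy bands fix the mass on the exact-match, genus-level and
    family-level grades (the genus band is split 70/15/15 between
    genus_correct, small_genus and very_close; the family band 70/30
    between family_correct and similar_genus).  The wrong-family rate,
    whose denominator excludes no-identification attempts, determines the
    no-id mass; the remainder is split 30/70 between good_try and
    unknown.  The repeat probability is set to C/4, the consistency score
    normalized to its attainable range.
    """
    p100, p80, p50 = pct_100 / 100, pct_ge_80 / 100, pct_ge_50 / 100
    mad, wrong = pct_mad / 100, pct_wrong / 100
    if not p100 <= p80 <= p50 <= 1:
        raise ConfigError(f"{tool_id}: accuracy percentages must nest")
    genus_band = p80 - p100
    family_band = p50 - p80
    remainder = 1.0 - p50 - mad
    if remainder < -_PROB_TOL:
        raise ConfigError(f"{tool_id}: %>=50 and %mad overlap past 100%")
    remainder = max(0.0, remainder)
    if wrong >= 1.0:
        raise ConfigError(f"{tool_id}: %wrong must be < 100")
    no_id = (remainder + mad - wrong) / (1.0 - wrong)
    no_id = min(max(no_id, 0.0), remainder)
    wrong_mass = remainder - no_id
    probs = {
        MatchCategory.SPECIES_CORRECT: p100,
        MatchCategory.GENUS_CORRECT: 0.70 * genus_band,
        MatchCategory.SMALL_GENUS: 0.15 * genus_band,
        MatchCategory.VERY_CLOSE: 0.15 * genus_band,
        MatchCategory.FAMILY_CORRECT: 0.70 * family_band,
        MatchCategory.SIMILAR_GENUS: 0.30 * family_band,
        MatchCategory.SIMILAR_FAMILY: 0.0,
        MatchCategory.GOOD_TRY: 0.30 * wrong_mass,
        MatchCategory.UNKNOWN: 0.70 * wrong_mass,
        MatchCategory.MISLEADING: mad,
        MatchCategory.NO_ID: no_id,
    }
    total = sum(probs.values())
    probs = {c: p / total for c, p in probs.items()}
    law = {1: 0.90, 2: 0.10} if single_answer else {1: 0.40, 2: 0.25, 3: 0.20, 4: 0.15}
    rho = min(1.0, max(0.0, mean_consistency / 4.0))
    return ToolProfile(tool_id, probs, law, rho)


def default_profiles() -> list[ToolProfile]:
    """Nine profiles spanning the published strong-to-weak app spectrum."""
    return [
        profile_from_summary(name, *summary, single_answer=name in _SINGLE_ANSWER_TOOLS)
        for name, summary in APP_SUMMARY.items()
    ]


def uniform_profiles(
    n_tools: int,
    category_probabilities: Mapping[MatchCategory, float],
    repeat_probability: float = 0.5,
    n_suggestions_law: Mapping[int, float] | None = None,
) -> list[ToolProfile]:
    """n tools sharing one behavioural profile (null-hypothesis design)."""
    law = n_suggestions_law or {1: 0.40, 2: 0.25, 3: 0.20, 4: 0.15}
    return [
        ToolProfile(f"tool{i + 1}", dict(category_probabilities), dict(law), repeat_probability)
        for i in range(n_tools)
    ]
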