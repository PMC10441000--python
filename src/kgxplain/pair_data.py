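"""Labeled drug-disease pairs: source merging, negative sampling, per-drug split."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TREAT = "treat"
NOT_TREAT = "not_treat"
UNKNOWN = "unknown"
LABELS = (NOT_TREAT, TREAT, UNKNOWN)


class PairValidationError(ValueError):
    pass


class SamplingError(RuntimeError):
    pass


@dataclass(frozen=True)
class LabeledPair:
    drug: str
    disease: str
    label: str
    sources: frozenset[str] = frozenset()
    split: str = "unassigned"

    @property
    def key(self) -> tuple[str, str]:
        return (self.drug, self.disease)


@dataclass(frozen=True)
class SplitConfig:
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")
        if any(r <= 0 for r in self.ratios):
            raise ValueError("split ratios must be positive")


def merge_labeled_sources(
    per_source_pairs: list[tuple[str, list[LabeledPair]]],
    drug_ids: set[str] | None = None,
    disease_ids: set[str] | None = None,
    conflict_log: list[tuple[str, str]] | None = None,
) -> list[LabeledPair]:
    """Union identical pairs across sources; drop cross-source label conflicts.

    A pair labelled treat by one source and not_treat by another is removed
    entirely and recorded in ``conflict_log``.
    """
    offenders = []
    if drug_ids is not None or disease_ids is not None:
        for _, pairs in per_source_pairs:
            for p in pairs:
                if drug_ids is not None and p.drug not in drug_ids:
                    offenders.append(p.drug)
                if disease_ids is not None and p.disease not in disease_ids:
                    offenders.append(p.disease)
    if offenders:
        raise PairValidationError(
            f"unmapped identifiers: {sorted(set(offenders))[:10]}"
        )

    merged: dict[tuple[str, str], dict] = {}
    for source, pairs in per_source_pairs:
        for p in pairs:
            if p.label not in (TREAT, NOT_TREAT):
                raise PairValidationError(
                    f"merge accepts only treat/not_treat labels, got {p.label!r}"
                )
            rec = merged.setdefault(p.key, {"labels": set(), "sources": set()})
            rec["labels"].add(p.label)
            rec["sources"].add(source)
            rec["sources"] |= set(p.sources)

    out: list[LabeledPair] = []
    for (drug, disease), rec in sorted(merged.items()):
        if len(rec["labels"]) > 1:
            if conflict_log is not None:
                conflict_log.append((drug, disease))
            logger.warning("label conflict for (%s, %s): dropped", drug, disease)
            continue
        out.append(
            LabeledPair(
                drug=drug,
                disease=disease,
                label=next(iter(rec["labels"])),
                sources=frozenset(rec["sources"]),
            )
        )
    return out


def sample_unknown_pairs(
    positives: list[LabeledPair],
    known: list[LabeledPair],
    drug_ids: set[str],
    disease_ids: set[str],
    seed: int = 0,
    max_attempts: int = 100,
) -> list[LabeledPair]:
    """One drug-replaced and one disease-replaced unknown pair per treat pair.

    Replacements are resampled until the candidate appears in neither the
    treat nor the not_treat class; output is deduplicated.
    """
    if len(drug_ids) < 2 or len(disease_ids) < 2:
        raise SamplingError("need at least 2 drugs and 2 diseases")
    rng = np.random.default_rng(seed)
    known_keys = {p.key for p in known}
    drugs = sorted(drug_ids)
    diseases = sorted(disease_ids)
    out: dict[tuple[str, str], LabeledPair] = {}
    for p in sorted({q.key for q in positives}):
        drug, disease = p
        for pool, make in (
            (drugs, lambda x: (x, disease)),
            (diseases, lambda x: (drug, x)),
        ):
            for attempt in range(max_attempts):
                cand = make(pool[rng.integers(len(pool))])
                if cand not in known_keys:
                    out.setdefault(
                        cand, LabeledPair(cand[0], cand[1], UNKNOWN)
                    )
                    break
            else:
                raise SamplingError(
                    f"could not sample a non-known replacement for {p} "
                    f"after {max_attempts} attempts"
                )
    return [out[k] for k in sorted(out)]


def _largest_remainder_counts(n: int, ratios: tuple[float, ...]) -> list[int]:
    raw = [n * r for r in ratios]
    counts = [int(x) for x in raw]
    rem = n - sum(counts)
    # distribute leftovers by descending fractional part, train-priority ties
    order = sorted(range(len(ratios)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:rem]:
        counts[i] += 1
    return counts


def split_by_drug(pairs: list[LabeledPair], cfg: SplitConfig) -> list[LabeledPair]:
    """Assign train/val/test per drug with largest-remainder 8/1/1 rounding.

    A drug with a single pair goes to train; with two pairs, train + test.
    Every drug seen in val/test is therefore also seen in train.
    """
    for p in pairs:
        if p.split != "unassigned":
            raise PairValidationError(f"pair {p.key} already assigned to {p.split}")
    rng = np.random.default_rng(cfg.seed)
    by_drug: dict[str, list[LabeledPair]] = {}
    for p in pairs:
        by_drug.setdefault(p.drug, []).append(p)

    out: list[LabeledPair] = []
    for drug in sorted(by_drug):
        group = sorted(by_drug[drug], key=lambda p: p.key)
        rng.shuffle(group)
        n = len(group)
        if n == 1:
            counts = [1, 0, 0]
        elif n == 2:
            counts = [1, 0, 1]
        else:
            counts = _largest_remainder_counts(n, cfg.ratios)
            if counts[0] == 0:  # keep the drug visible in training
                donor = max(range(1, 3), key=lambda i: counts[i])
                counts[donor] -= 1
                counts[0] += 1
        names = ["train"] * counts[0] + ["val"] * counts[1] + ["test"] * counts[2]
        for p, split in zip(group, names):
            out.append(replace(p, split=split))
    out.sort(key=lambda p: p.key)
    return out


# -- I/O -----------------------------------------------------------------

PAIR_COLUMNS = ("drug", "disease", "label", "sources", "split")


def save_pairs(pairs: list[LabeledPair], path: str) -> None:
    pd.DataFrame(
        [
            (p.drug, p.disease, p.label, "|".join(sorted(p.sources)), p.split)
            for p in pairs
        ],
        columns=list(PAIR_COLUMNS),
    ).to_csv(path, sep="\t", index=False)


def load_pairs(path: str) -> list[LabeledPair]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = {"drug", "disease", "label"} - set(df.columns)
    if missing:
        raise PairValidationError(f"pair table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        sources = frozenset(s for s in getattr(row, "sources", "").split("|") if s)
        split = getattr(row, "split", "") or "unassigned"
        out.append(LabeledPair(row.drug, row.disease, row.label, sources, split))
    return out
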