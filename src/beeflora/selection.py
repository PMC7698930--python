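"""Resource-selection analysis of pollen loads.

Availability (PA) is the occurrence frequency of a plant taxon among all
(taxon, sampling point) flora records; harvest rate (HR) the frequency of a
pollen taxon among pollen records.  Selection is quantified per taxon by
the index D = (HR - PA) / (HR + PA - 2 HR PA) in [-1, 1], with percentile
bootstrap confidence intervals obtained by resampling bees (each with its
whole pollen load) with replacement while holding PA fixed.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable

import numpy as np
import pandas as pd

from .data import (
    Dataset,
    InsufficientDataError,
    ValidationError,
    normalize_taxon,
)

logger = logging.getLogger("beeflora")

#: HR denominator conventions: total pollen records, or number of bees examined
HR_DENOMINATORS = ("records", "bees")


def pollen_availability(
    dataset: Dataset,
    included_taxa: Iterable[str] | None = None,
    *,
    entomophilous_only: bool = True,
) -> pd.Series:
    """Per-taxon availability PA over the included taxa.

    PA_i = (#sampling points where taxon i occurs) / (total number of
    (taxon, point) records among included taxa), so PA sums to 1 over taxa
    with at least one record.  Default inclusion: taxa found on bees that
    also occur in the flora.
    """
    presence = dataset.plant_presence(entomophilous_only=entomophilous_only)
    presence = presence.assign(key=presence["taxon"].map(normalize_taxon))
    if included_taxa is None:
        carried = {normalize_taxon(t) for t in dataset.pollen["pollen_taxon"].unique()}
        flora = set(presence["key"])
        keys = sorted(carried & flora)
        names = (
            presence.drop_duplicates("key").set_index("key")["taxon"].loc[keys].tolist()
        )
    else:
        names = list(dict.fromkeys(included_taxa))
        keys = [normalize_taxon(t) for t in names]
    if not names:
        raise InsufficientDataError("no taxa to include in availability")

    counts = presence[presence["key"].isin(set(keys))].groupby("key").size()
    total = int(counts.sum())
    if total == 0:
        raise InsufficientDataError("included taxa have zero flora records")
    pa = pd.Series(
        [counts.get(k, 0) / total for k in keys], index=pd.Index(names, name="taxon"),
        name="PA", dtype=float,
    )
    return pa


def harvest_rate(dataset: Dataset, denominator: str = "records") -> pd.Series:
    """Per-taxon harvest rate HR.

    HR_i = (#bees carrying taxon i) / denominator.  With the default
    ``"records"`` denominator (total pollen records) HR sums to 1; the
    ``"bees"`` convention divides by the number of distinct bees carrying
    any pollen instead.
    """
    if denominator not in HR_DENOMINATORS:
        raise ValidationError(f"denominator must be one of {HR_DENOMINATORS}")
    pollen = dataset.pollen
    if pollen.empty:
        raise InsufficientDataError("no pollen records")
    counts = pollen.groupby("pollen_taxon")["bee_id"].nunique()
    if denominator == "records":
        denom = len(pollen)
    else:
        denom = pollen["bee_id"].nunique()
    hr = (counts / denom).astype(float)
    hr.index.name = "taxon"
    hr.name = "HR"
    return hr.sort_index()


def jacobs_index(hr: float, pa: float) -> float:
    """Selection index D = (HR - PA) / (HR + PA - 2 HR PA), in [-1, 1]."""
    hr, pa = float(hr), float(pa)
    denom = hr + pa - 2.0 * hr * pa
    if denom == 0.0:
        raise ValidationError(
            f"Jacobs index undefined for HR={hr}, PA={pa} (degenerate denominator)"
        )
    return (hr - pa) / denom


def _jacobs_vector(hr: np.ndarray, pa: np.ndarray) -> np.ndarray:
    denom = hr + pa - 2.0 * hr * pa
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(denom != 0.0, (hr - pa) / np.where(denom == 0.0, 1.0, denom), np.nan)
    return d


def bootstrap_selection(
    dataset: Dataset,
    n_boot: int = 5000,
    seed: int = 0,
    *,
    hr_denominator: str = "records",
    included_taxa: Iterable[str] | None = None,
    ci: tuple[float, float] = (2.5, 97.5),
    entomophilous_only: bool = True,
) -> pd.DataFrame:
    """Per-taxon selection results with bootstrap percentile CIs.

    Each replicate resamples bees (with their full pollen loads) with
    replacement and recomputes HR and D against the fixed PA.  Pollen taxa
    absent from the flora are excluded from D and returned in
    ``attrs['absent_from_flora']``.  Columns: PA, HR, D, ci_low, ci_high,
    n_boot, selection_class, habitat_provenance, unstable, ci_excludes_point.
    """
    if n_boot < 2:
        raise ValidationError("n_boot must be >= 2")
    if dataset.pollen.empty:
        raise InsufficientDataError("no pollen records")
    logger.info("bootstrap_selection: n_boot=%d seed=%d", n_boot, seed)

    pa = pollen_availability(
        dataset, included_taxa, entomophilous_only=entomophilous_only
    )
    pa_keys = {normalize_taxon(t): t for t in pa.index}
    pollen = dataset.pollen.assign(
        key=dataset.pollen["pollen_taxon"].map(normalize_taxon)
    )
    absent = sorted(
        {t for t, k in zip(pollen["pollen_taxon"], pollen["key"]) if k not in pa_keys}
    )
    pollen = pollen[pollen["key"].isin(pa_keys)]
    if pollen.empty:
        raise InsufficientDataError("no pollen taxa match the flora after harmonization")

    taxa = list(pa.index)
    taxon_pos = {normalize_taxon(t): i for i, t in enumerate(taxa)}

    # bee x taxon presence matrix over bees with >= 1 matching pollen record
    bee_ids = sorted(pollen["bee_id"].unique())
    bee_pos = {b: i for i, b in enumerate(bee_ids)}
    loads = np.zeros((len(bee_ids), len(taxa)), dtype=np.int64)
    for _, row in pollen.iterrows():
        loads[bee_pos[row["bee_id"]], taxon_pos[row["key"]]] = 1

    pa_vec = pa.to_numpy()
    records_per_bee = loads.sum(axis=1)

    def hr_from_counts(bee_weights: np.ndarray) -> np.ndarray:
        numer = bee_weights @ loads
        if hr_denominator == "records":
            denom = bee_weights @ records_per_bee
        elif hr_denominator == "bees":
            denom = bee_weights.sum(axis=-1)
        else:
            raise ValidationError(f"denominator must be one of {HR_DENOMINATORS}")
        denom = np.where(denom == 0, 1, denom)
        return numer / denom[..., None] if numer.ndim > 1 else numer / denom

    hr_vec = hr_from_counts(np.ones(len(bee_ids), dtype=np.int64))
    d_vec = _jacobs_vector(hr_vec, pa_vec)

    # bootstrap: multinomial bee-resampling weights, fully vectorized
    rng = np.random.default_rng(seed)
    weights = rng.multinomial(
        len(bee_ids), np.full(len(bee_ids), 1.0 / len(bee_ids)), size=n_boot
    )
    boot_hr = hr_from_counts(weights)  # (n_boot, n_taxa)
    boot_d = _jacobs_vector(boot_hr, np.broadcast_to(pa_vec, boot_hr.shape))

    lo_q, hi_q = ci[0] / 100.0, ci[1] / 100.0
    with warnings.catch_warnings():
        # degenerate taxa (HR=PA=1) have all-NaN replicates; report NaN CIs
        warnings.simplefilter("ignore", RuntimeWarning)
        ci_low = np.nanquantile(boot_d, lo_q, axis=0)
        ci_high = np.nanquantile(boot_d, hi_q, axis=0)
    dropped_frac = (boot_hr == 0).mean(axis=0)

    provenance = _habitat_provenance(dataset, taxa, entomophilous_only)
    classes = np.where(ci_low > 0, "over_selected",
                       np.where(ci_high < 0, "under_selected", "neutral"))
    result = pd.DataFrame({
        "taxon": taxa,
        "PA": pa_vec,
        "HR": hr_vec,
        "D": d_vec,
        "ci_low": ci_low,
        "ci_high": ci_high,
        "n_boot": n_boot,
        "selection_class": classes,
        "habitat_provenance": [";".join(sorted(provenance.get(t, ()))) for t in taxa],
        "unstable": dropped_frac > 0.5,
        "ci_excludes_point": (d_vec < ci_low) | (d_vec > ci_high),
    })
    if result["ci_excludes_point"].any():
        bad = result.loc[result["ci_excludes_point"], "taxon"].tolist()
        logger.warning("percentile CI excludes point estimate for %s", bad)
    result.attrs["absent_from_flora"] = absent
    result.attrs["seed"] = seed
    return result.sort_values("D", ascending=False, ignore_index=True)


def _habitat_provenance(
    dataset: Dataset, taxa: list[str], entomophilous_only: bool
) -> dict[str, frozenset[str]]:
    presence = dataset.plant_presence(entomophilous_only=entomophilous_only)
    habitat = dataset.habitat_of()
    presence = presence.assign(
        key=presence["taxon"].map(normalize_taxon),
        habitat=presence["point_id"].map(habitat),
    )
    by_key = presence.groupby("key")["habitat"].agg(lambda s: frozenset(s))
    return {t: by_key.get(normalize_taxon(t), frozenset()) for t in taxa}
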