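"""Synthetic drug × kinase activity matrices with controllable specificity.

The generator emulates a kinase-inhibitor selectivity panel: most drugs
hit most kinases weakly (background drawn from a heavy-tailed
distribution), while designated "spiked" drugs are engineered to be
markedly more potent on a chosen target set by at least a multiplicative
potency-gap factor.  Kd values are drawn log-normal (published Kd panels
span several orders of magnitude); percent-inhibition values are drawn
from a scaled Beta and clipped to [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ActivityMatrix, AssayType

__all__ = ["Spike", "FixtureSpec", "generate", "write_long_tsv"]


@dataclass(frozen=True)
class Spike:
    """One engineered drug-target specificity: ``drug`` is at least
    ``gap``-fold more potent on every kinase in ``targets`` than on any
    of its background kinases."""

    drug: str
    targets: frozenset[str]
    gap: float = 100.0


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic activity matrix.

    Kd background is log-normal with ``kd_log10_loc`` (log10 μM; 0.0 →
    median 1 μM) and ``kd_log10_scale`` decades of spread.  Percent
    inhibition background is ``100·Beta(inhib_alpha, inhib_beta)``.
    """

    n_drugs: int = 20
    n_kinases: int = 100
    assay_type: AssayType = "kd"
    seed: int = 0
    spikes: tuple[Spike, ...] = ()
    kd_log10_loc: float = 0.0
    kd_log10_scale: float = 1.0
    inhib_alpha: float = 2.0
    inhib_beta: float = 5.0
    drug_prefix: str = "drug"
    kinase_prefix: str = "KIN"
    extra_kinases: tuple[str, ...] = field(default_factory=tuple)


def _names(prefix: str, n: int, width: int = 3) -> list[str]:
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def generate(spec: FixtureSpec) -> ActivityMatrix:
    """Draw a matrix satisfying the spike invariant, reproducibly per seed.

    Spiked target kinases absent from the generated panel are appended
    as extra columns; a target set larger than the kinase panel is an
    error.
    """
    rng = np.random.default_rng(spec.seed)
    kinases = _names(spec.kinase_prefix, spec.n_kinases)
    extra = [k for s in spec.spikes for k in sorted(s.targets)
             if k not in kinases]
    extra += [k for k in spec.extra_kinases if k not in kinases]
    # keep the panel size as requested: extras replace trailing columns
    seen: list[str] = []
    for k in extra:
        if k not in seen:
            seen.append(k)
    if len(seen) > spec.n_kinases:
        raise ValueError(
            f"{len(seen)} spiked/extra kinases exceed panel size "
            f"{spec.n_kinases}"
        )
    kinases = kinases[: spec.n_kinases - len(seen)] + sorted(seen)
    drugs = _names(spec.drug_prefix, spec.n_drugs)
    spike_map = {s.drug: s for s in spec.spikes}
    unknown = set(spike_map) - set(drugs)
    if unknown:
        drugs = drugs[: spec.n_drugs - len(unknown)] + sorted(unknown)

    if spec.assay_type == "kd":
        values = 10.0 ** rng.normal(
            spec.kd_log10_loc, spec.kd_log10_scale,
            size=(spec.n_drugs, len(kinases)),
        )
    else:
        values = 100.0 * rng.beta(
            spec.inhib_alpha, spec.inhib_beta,
            size=(spec.n_drugs, len(kinases)),
        )
    df = pd.DataFrame(values, index=drugs, columns=kinases)

    for spike in spec.spikes:
        missing = spike.targets - set(kinases)
        if missing:
            raise ValueError(f"spike targets not in panel: {sorted(missing)}")
        targets = sorted(spike.targets)
        background = [k for k in kinases if k not in spike.targets]
        if spec.assay_type == "kd":
            best_bg = df.loc[spike.drug, background].min()
            # nudge below the exact quotient so background/target >= gap
            # holds despite float rounding
            df.loc[spike.drug, targets] = np.nextafter(
                best_bg / spike.gap, 0.0
            )
        else:
            # hold targets near full inhibition and compress the
            # background below spike_value/gap to honor the gap factor
            spike_value = 99.0
            cap = spike_value / spike.gap
            bg = df.loc[spike.drug, background]
            df.loc[spike.drug, background] = bg / 100.0 * cap
            df.loc[spike.drug, targets] = spike_value
    return ActivityMatrix(values=df, assay_type=spec.assay_type)


def write_long_tsv(matrix: ActivityMatrix, path: str | Path) -> None:
    """Serialize a matrix as the long-format TSV the loader consumes."""
    path = Path(path)
    long_df = (
        matrix.values.stack()
        .rename_axis(["drug", "kinase"])
        .reset_index(name="value")
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# synthetic activity matrix, assay_type={matrix.assay_type}\n")
        long_df.to_csv(fh, sep="\t", header=False, index=False)
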