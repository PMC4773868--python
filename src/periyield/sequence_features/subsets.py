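"""Built-in curated feature subsets for the four prediction tasks.

These are the published subsets selected for the primary classification
task and the three class-specific regression tasks.  ``named_subset``
computes each entry directly from its definition (frequencies, runs,
dipeptide counts, products), independently of the assembled full vector;
``subset_feature_names`` maps the same entries onto full-vector feature
names so a trained model can index them from an extracted matrix.
"""

from __future__ import annotations

from typing import Mapping

from ..errors import InvalidArgumentError
from .extract import (
    aa_composition,
    abs_charge_per_residue,
    isoelectric_point,
    max_consecutive_run,
    predicted_properties,
)
from .properties import PropertyPredictorSuite
from .records import SequenceRecord
from .registry import FeatureRegistry

TASKS = ("classification", "reg_high", "reg_medium", "reg_low")

#: Short display names per task, in publication order.
SUBSET_SHORT_NAMES: Mapping[str, tuple[str, ...]] = {
    "classification": ("BPC", "Sulfur", "MCBPC", "logPFR", "CL", "QD", "VE"),
    "reg_high": ("TP", "VT", "TxMCPhe"),
    "reg_medium": ("ER", "WQ", "VT", "RxAbsCharge", "ANCxMCAliphatic", "MCCysxpI"),
    "reg_low": ("FxlogPFR", "SxMCNPH", "Yxtransmembrane", "YxnlogPFR"),
}


def _dipeptide_count(sequence: str, pair: str) -> float:
    count = 0
    for pos in range(len(sequence) - 1):
        if sequence[pos : pos + 2] == pair:
            count += 1
    return float(count)


def named_subset(
    record: SequenceRecord,
    task: str,
    suite: PropertyPredictorSuite | None = None,
    registry: FeatureRegistry | None = None,
    tyrosine_count_variant: bool = False,
) -> dict[str, float]:
    """Compute the curated subset for ``task`` directly from definitions.

    ``tyrosine_count_variant`` switches the tyrosine x transmembrane entry
    of the low regression subset from occurrence *frequency* (the default,
    which cross-indexes into the full vector) to raw occurrence *count*;
    the source description is ambiguous between the two.
    """
    if task not in TASKS:
        raise InvalidArgumentError(f"unknown task {task!r}; expected one of {TASKS}")
    suite = suite or PropertyPredictorSuite.default()
    registry = registry or FeatureRegistry()
    seq = record.sequence
    freq = aa_composition(record)
    props = predicted_properties(record, suite)

    def run(group_name: str) -> float:
        return float(max_consecutive_run(record, registry.group(group_name)))

    if task == "classification":
        return {
            "BPC": freq["H"] + freq["K"] + freq["R"],
            "Sulfur": freq["C"] + freq["M"],
            "MCBPC": run("basic_positive"),
            "logPFR": props["logPFR"],
            "CL": _dipeptide_count(seq, "CL"),
            "QD": _dipeptide_count(seq, "QD"),
            "VE": _dipeptide_count(seq, "VE"),
        }
    if task == "reg_high":
        return {
            "TP": _dipeptide_count(seq, "TP"),
            "VT": _dipeptide_count(seq, "VT"),
            "TxMCPhe": freq["T"] * _single_residue_run(record, "F"),
        }
    if task == "reg_medium":
        return {
            "ER": _dipeptide_count(seq, "ER"),
            "WQ": _dipeptide_count(seq, "WQ"),
            "VT": _dipeptide_count(seq, "VT"),
            "RxAbsCharge": freq["R"] * abs_charge_per_residue(record),
            "ANCxMCAliphatic": (freq["D"] + freq["E"]) * run("aliphatic"),
            "MCCysxpI": _single_residue_run(record, "C") * isoelectric_point(record),
        }
    # reg_low
    tyrosine = seq.count("Y") if tyrosine_count_variant else freq["Y"]
    return {
        "FxlogPFR": freq["F"] * props["logPFR"],
        "SxMCNPH": freq["S"] * run("nonpolar_hydrophilic"),
        "Yxtransmembrane": tyrosine * props["transmembrane"],
        "YxnlogPFR": freq["Y"] * props["nlogPFR"],
    }


def _single_residue_run(record: SequenceRecord, residue: str) -> float:
    from .records import ResidueGroup

    return float(max_consecutive_run(record, ResidueGroup(residue, frozenset(residue))))


def subset_feature_names(task: str, registry: FeatureRegistry | None = None) -> list[str]:
    """Full-vector feature names corresponding to the curated subset."""
    if task not in TASKS:
        raise InvalidArgumentError(f"unknown task {task!r}; expected one of {TASKS}")
    registry = registry or FeatureRegistry()
    ix = registry.interactive_name
    if task == "classification":
        return [
            "gfreq_basic_positive",
            "gfreq_sulfur",
            "grun_basic_positive",
            "logPFR",
            "dp_CL",
            "dp_QD",
            "dp_VE",
        ]
    if task == "reg_high":
        return ["dp_TP", "dp_VT", ix("freq_T", "run_F")]
    if task == "reg_medium":
        return [
            "dp_ER",
            "dp_WQ",
            "dp_VT",
            ix("freq_R", "abs_charge_per_residue"),
            ix("gfreq_acidic_negative", "grun_aliphatic"),
            ix("run_C", "isoelectric_point"),
        ]
    return [
        ix("freq_F", "logPFR"),
        ix("freq_S", "grun_nonpolar_hydrophilic"),
        ix("freq_Y", "transmembrane"),
        ix("freq_Y", "nlogPFR"),
    ]
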