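"""Harmonize and QC-filter the merged genus table.

Applies the depth filter (samples with fewer than 100 reads dropped) and
per-study contaminant removal, writes the read-retention ledger and the
relative-abundance table, and reports the cohort summary.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _paths import QC, SYNTH

from bloodsig.io import read_feature_table, read_metadata, summarize_cohorts, write_feature_table
from bloodsig.qc import QCAccounting, filter_low_depth, remove_contaminants, to_relative_abundance


def main():
    QC.mkdir(parents=True, exist_ok=True)
    table = read_feature_table(SYNTH / "feature_table.tsv")
    metadata = read_metadata(SYNTH / "metadata.tsv")
    contaminants = pd.read_csv(SYNTH / "contaminants.tsv", sep="\t")

    cohorts = summarize_cohorts(metadata)
    print(
        f"{cohorts['n_studies']} studies, {cohorts['n_control']} Ct / "
        f"{cohorts['n_case']} NCt samples "
        f"(per-study controls {cohorts['min_control']}..{cohorts['max_control']})"
    )

    acct = QCAccounting()
    filtered, _ = filter_low_depth(table, 100, acct)
    sample_study = metadata.set_index("sample_id")["study_id"]
    cleaned, _ = remove_contaminants(filtered, contaminants, sample_study, accounting=acct)
    acct.validate()

    ledger = acct.to_frame()
    print(ledger.to_string(index=False))
    print(f"retained {acct.final_reads}/{acct.initial_reads} reads "
          f"({acct.final_reads / acct.initial_reads:.1%})")

    write_feature_table(cleaned, QC / "filtered_table.tsv")
    to_relative_abundance(cleaned).to_csv(QC / "relative_abundance.tsv", sep="\t")
    ledger.to_csv(QC / "read_accounting.tsv", sep="\t", index=False)
    acct.to_json(QC / "read_accounting.json")
    print(f"outputs -> {QC}")


if __name__ == "__main__":
    main()
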