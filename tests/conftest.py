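from pathlib import Path

import pytest


def write_quarter(
    directory: Path,
    quarter: str = "18Q1",
    demo_rows: list[str] = (),
    drug_rows: list[str] = (),
    reac_rows: list[str] = (),
    demo_header: str = "primaryid$caseid$caseversion$fda_dt",
    drug_header: str = "primaryid$drug_seq$drugname$role_cod",
    reac_header: str = "primaryid$pt",
) -> Path:
    """Write one FAERS-dialect quarterly file set into `directory`."""
    directory.mkdir(parents=True, exist_ok=True)
    (directory / f"DEMO{quarter}.txt").write_text("\n".join([demo_header, *demo_rows]) + "\n")
    (directory / f"DRUG{quarter}.txt").write_text("\n".join([drug_header, *drug_rows]) + "\n")
    (directory / f"REAC{quarter}.txt").write_text("\n".join([reac_header, *reac_rows]) + "\n")
    return directory


@pytest.fixture
def tiny_quarter(tmp_path: Path) -> Path:
    """Four cases: {drug+event}, {drug}, {event}, {neither} -> a=b=c=d=1."""
    return write_quarter(
        tmp_path / "faers",
        demo_rows=[
            "101$1$1$20190101",
            "201$2$1$20190102",
            "301$3$1$20190103",
            "401$4$1$20190104",
        ],
        drug_rows=[
            "101$1$SPIRIVA$PS",
            "201$1$SPIRIVA$PS",
            "301$1$OTHERDRUG$PS",
            "401$1$OTHERDRUG$PS",
        ],
        reac_rows=[
            "101$Dyspnoea",
            "301$Dyspnoea",
            "201$Cough",
            "401$Cough",
        ],
    )
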