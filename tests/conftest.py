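import pytest

from faers_signals.synthetic import SimConfig, generate, write_bundle


@pytest.fixture(scope="session")
def small_sim():
    """A 500-case synthetic bundle with one planted signal and duplicates."""
    cfg = SimConfig(
        seed=20240,
        n_cases=500,
        n_pts=50,
        n_drugs=20,
        target_drug_share=0.2,
        planted_signals=(("PT_0005", 4.0),),
        duplicate_rate=0.1,
        partial_date_rate=0.05,
        missing_demo_rate=0.2,
    )
    bundle, truth = generate(cfg)
    return cfg, bundle, truth


@pytest.fixture(scope="session")
def small_sim_files(small_sim, tmp_path_factory):
    cfg, bundle, truth = small_sim
    out = tmp_path_factory.mktemp("bundle")
    paths = write_bundle(bundle, truth, out)
    table_paths = [p for p in paths if p.name != "truth.tsv"]
    return cfg, bundle, truth, table_paths


def write_tiny_bundle(tmp_path, demo_rows, drug_rows=(), reac_rows=(),
                      ther_rows=(), outc_rows=()):
    """Write handcrafted '$'-delimited FAERS table files."""
    spec = {
        "DEMO": ("primaryid$caseid$fda_dt$event_dt$age$age_cod$sex$wt$wt_cod$"
                 "occp_cod$occr_country$reporter_country", demo_rows),
        "DRUG": ("primaryid$caseid$drug_seq$role_cod$drugname", drug_rows),
        "REAC": ("primaryid$caseid$pt", reac_rows),
        "THER": ("primaryid$caseid$dsg_drug_seq$start_dt$end_dt", ther_rows),
        "OUTC": ("primaryid$caseid$outc_cod", outc_rows),
    }
    paths = []
    for name, (header, rows) in spec.items():
        p = tmp_path / f"{name}_test.txt"
        p.write_text("\n".join([header, *rows]) + "\n")
        paths.append(p)
    return paths
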