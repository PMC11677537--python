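import pytest
from hypothesis import HealthCheck, settings

from metex14 import (Exon, GeneModel, WindowConfig, build_published_fixture,
                     classify_cohort, concordance_summary, default_met_model)

settings.register_profile(
    "default", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture])
settings.load_profile("default")


@pytest.fixture()
def toy_model() -> GeneModel:
    """Small plus-strand three-exon model with exon 14 = [115000, 115140]."""
    return GeneModel(
        gene_symbol="MET", chromosome="7", strand="+", transcript_id="TOY",
        exons=(Exon(13, 114500, 114650), Exon(14, 115000, 115140),
               Exon(15, 118000, 118200)),
    )


@pytest.fixture()
def toy_window_cfg() -> WindowConfig:
    return WindowConfig(25, 2, 2, 10)


@pytest.fixture(scope="session")
def fixture_cohort():
    return build_published_fixture()


@pytest.fixture(scope="session")
def fixture_pipeline(fixture_cohort):
    """Classifier + concordance run over the deterministic fixture cohort."""
    model, wcfg = default_met_model()
    calls, coverage, audit = classify_cohort(
        fixture_cohort.variants, fixture_cohort.fusions, model, wcfg,
        patients=fixture_cohort.patients)
    stats = concordance_summary(
        calls, coverage,
        lowread_denominator=fixture_cohort.manifest["lowread_percent_denominator"])
    return {"calls": calls, "coverage": coverage, "audit": audit, "stats": stats}
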