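import pytest
from hypothesis import HealthCheck, settings

from alteredself import PeptideRecord, RepertoirePair

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def toy_pair() -> RepertoirePair:
    """Three-peptide pool: one disappearing, one unchanged, one novel viral.

    With p = 1/2 the seven nonempty Bernoulli subsets are equally weighted
    and give category probabilities decrease 4/7, increase 2/7, equal 1/7
    (frozen from exhaustive enumeration by hand).
    """
    records = [
        PeptideRecord("AAAAAAAAA", 2.0, 0.0, origin="self", hla_allele="C*07:02"),
        PeptideRecord("CCCCCCCCC", 1.0, 1.0, origin="self", hla_allele="C*07:02"),
        PeptideRecord("DDDDDDDDD", 0.0, 1.0, origin="viral", hla_allele="C*07:02"),
    ]
    return RepertoirePair.from_records("toy", records)


@pytest.fixture
def small_pair() -> RepertoirePair:
    """Hand-built mixed repertoire covering origins, lengths, and alleles."""
    records = [
        PeptideRecord("KLAEVFGSR", 10.0, 5.0, origin="self", hla_allele="A*03:01"),
        PeptideRecord("YLFDEWGSK", 3.0, 0.0, origin="self", hla_allele="B*57:01"),
        PeptideRecord("AVDPIKGHW", 2.0, 4.0, origin="self", hla_allele="A*02:01"),
        PeptideRecord("QQWNAHTL", 1.0, 1.0, origin="self", hla_allele="NA"),
        PeptideRecord("MMRSTWQCA", 0.0, 6.0, origin="viral", hla_allele="C*04:01"),
    ]
    return RepertoirePair.from_records("small", records)
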