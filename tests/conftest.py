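import pandas as pd
import pytest

from labelaudit.synthetic_data import (
    StudyDesign,
    demo_reference,
    generate_products,
)


@pytest.fixture(scope="session")
def ref():
    return demo_reference()


@pytest.fixture(scope="session")
def cohort():
    """Default-design cohort with ground truth (seed 11)."""
    products, truth = generate_products(StudyDesign(seed=11))
    return products, truth


def perfect_calls(truth: pd.DataFrame) -> pd.DataFrame:
    """Species-call table assuming error-free barcoding of the truth."""
    return pd.DataFrame(
        {
            "sample_id": truth["sample_id"],
            "status": "assigned",
            "species": truth["true_species"],
        }
    )


@pytest.fixture(scope="session")
def adjudicated(ref, cohort):
    from labelaudit.adjudication import adjudicate_cohort

    products, truth = cohort
    return adjudicate_cohort(
        products,
        perfect_calls(truth),
        ref,
        ("comprehensive", "afns", "strict_flake", "lenient_flake"),
    )
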