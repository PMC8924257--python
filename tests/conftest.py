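import hypothesis
from hypothesis import strategies as st

hypothesis.settings.register_profile(
    "default", max_examples=50, deadline=None, derandomize=True
)
hypothesis.settings.load_profile("default")


def dna(min_size: int = 1, max_size: int = 60, alphabet: str = "ACGT"):
    """Strategy for DNA strings."""
    return st.text(alphabet=sorted(alphabet), min_size=min_size, max_size=max_size)
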