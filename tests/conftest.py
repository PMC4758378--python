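import warnings

from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# small-permutation warnings are exercised deliberately in several tests
warnings.filterwarnings("ignore", message="n_perm=.* is small")
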