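# Material table of the lumbar FE model: Young's modulus (MPa), Poisson
# ratio and the constitutive tag carried as metadata.  All parts are solved
# as isotropic linear elastic; the nucleus' nu = 0.5 is clamped to 0.4999
# at binding time.
- {name: Cortical bone, elastic_modulus_MPa: 12000.0, poisson_ratio: 0.3, constitutive_tag: linear elastic}
- {name: Outer layer of fibrous ring, elastic_modulus_MPa: 550.0, poisson_ratio: 0.3, constitutive_tag: transversely isotropic linear elastic}
- {name: Fiber ring second layer, elastic_modulus_MPa: 490.0, poisson_ratio: 0.3, constitutive_tag: transversely isotropic linear elastic}
- {name: Fiber ring third layer, elastic_modulus_MPa: 440.0, poisson_ratio: 0.3, constitutive_tag: transversely isotropic linear elastic}
- {name: Cancellous bone, elastic_modulus_MPa: 100.0, poisson_ratio: 0.2, constitutive_tag: hyperelastic}
- {name: Cartilaginous endplate, elastic_modulus_MPa: 25.0, poisson_ratio: 0.3, constitutive_tag: linear elastic}
- {name: Ligamentum flavum, elastic_modulus_MPa: 15.0, poisson_ratio: 0.3, constitutive_tag: linear elastic}
- {name: Posterior longitudinal ligament, elastic_modulus_MPa: 10.0, poisson_ratio: 0.3, constitutive_tag: linear elastic}
- {name: Interspinous ligament, elastic_modulus_MPa: 10.0, poisson_ratio: 0.3, constitutive_tag: linear elastic}
- {name: Intertransvers ligament, elastic_modulus_MPa: 10.0, poisson_ratio: 0.3, constitutive_tag: linear elastic}
- {name: Supraspinal ligament, elastic_modulus_MPa: 8.0, poisson_ratio: 0.3, constitutive_tag: linear elastic}
- {name: Anterior longitudinal, elastic_modulus_MPa: 8.0, poisson_ratio: 0.3, constitutive_tag: linear elastic}
- {name: Nucleus pulposus, elastic_modulus_MPa: 1.0, poisson_ratio: 0.5, constitutive_tag: linear elastic}
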