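[world]
n_patches = 12
n_individuals = 100
n_generations = 300
patch_type_assignment = [1, 1, 1, 1, 1, 1, 2, 2, 2, 2, 2, 2]
seed = 0

[lifecycle]
t_before = 10
t_after = 10
dispersal_mortality = 0.01
learning_cost = 1.4
competition_factor = 2.0

[mutation]
mutation_prob = 0.1
mutation_sd = 0.1

[extinction]
extinction_every = 2
extinction_count = 1

[[resources]]
resource_id = 1
value = 1.0
handling_time = 1.0
detectability = 0.5

[[resources]]
resource_id = 2
value = 10.0
handling_time = 300.0
detectability = 0.5

[[resources]]
resource_id = 3
value = 10.0
handling_time = 300.0
detectability = 0.5

[[patch_types]]
patch_type_id = 1
abundances = { "1" = 1.0, "2" = 5.0 }

[[patch_types]]
patch_type_id = 2
abundances = { "1" = 1.0, "3" = 5.0 }
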