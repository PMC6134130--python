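K_bmal_act: 4.26720485553235
K_bmal_exo: 0.17250168948113315
K_cplx: 4.198679918205225
K_cplx_exo: 4.43339461424192
K_exo_sec: 31.42644600315188
K_glu_per: 1.4562973713109497
K_glu_sec: 0.7247770544905723
K_rev_rep: 3.3154706358692465
c_glu: 3.2063345548316273
cneur: 1.4336
d_bmal_m: 0.1961926108154543
d_bmal_p: 0.3164580161452982
d_complex: 0.10997081332406446
d_cry_m: 0.24049737741883767
d_cry_p: 0.19704707898415558
d_exo_m: 0.611976384003105
d_exo_p: 1.3474239942808761
d_f1: 0.9927699187089686
d_f2: 3.292091966277283
d_glu: 0.61803351396719
d_i: 0.9872265476912607
d_per_m: 0.9515349766618945
d_per_p: 0.22390511007107705
d_rev_m: 0.29767229352523655
d_rev_p: 0.3030934141068431
g_base: 0.2848395961137015
k_assoc: 2.603583039707535
k_bmal: 0.3626380281058955
k_cry: 0.39900206341090805
k_dissoc: 0.0397884728580648
k_exo: 0.22750223405377257
k_f1: 4.246183423157732
k_f2: 2.217465293193021
k_food_glu: 0.3789031253100912
k_i: 1.2597129277199803
k_ins_glu: 2.4582509258062433
k_per: 0.6122365832706341
k_rev: 0.2967686426386336
n_bmal_act: 3.0
n_bmal_exo: 2.2916233814797966
n_cplx: 8.0
n_cplx_exo: 5.940990092172533
n_exo_sec: 2.554319654278456
n_glu_per: 4.0
n_glu_sec: 1.8573417518517887
n_rev_rep: 3.0
scn_peak: 0.5066569516192171
v_bmal: 4.7977902318867915
v_cry: 2.0857782845846384
v_exo: 66.4535903104386
v_per: 1.3200487614576863
v_rev: 29.991515012076725
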