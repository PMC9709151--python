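animal_id,behavior,testing_date,result,observed_response
Charlie,vocalization,2021-06-28,Success,vocalization
Charlie,lift_left_leg,2021-08-15,Success,lift_left_leg
Charlie,move_ring_into_lid,2021-09-16,Lifted leg,lift_left_leg
Mr Huang,vocalization,2021-06-30,Success,vocalization
Mr Huang,lift_left_leg,2021-08-15,Lifted right leg,lift_right_leg
Mr Huang,move_ring_into_lid,2021-09-29,Success,move_ring_into_lid
Gargamel,vocalization,2021-09-05,Success,vocalization
Gargamel,lift_left_leg,2021-09-11,Lifted right leg,lift_right_leg
Gargamel,move_ring_into_lid,2021-10-04,Success,move_ring_into_lid
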